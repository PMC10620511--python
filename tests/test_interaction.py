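"""Competitive interaction model, psi estimation and surface classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combopd import (
    CombinationParams,
    DesignSpec,
    DomainError,
    EstimationError,
    HillParams,
    InteractionModel,
    additive_surface,
    classify_against_surface,
    competitive_response,
    generate_static,
    hill_response,
)
from combopd.interaction import surface_frame
from combopd.datasets import DEX_GRID, DOX_GRID
from combopd.reference import STATIC_PSI, static_combination

SIMPLE = CombinationParams(HillParams(100, 1, 1), HillParams(100, 1, 2))


def test_no_drug_returns_baseline():
    assert competitive_response(SIMPLE, 0.0, 0.0) == SIMPLE.r0


def test_reduces_to_single_agent_hill_at_zero_partner():
    """With conc_b = 0 and psi = 1 the combination model collapses to the
    plain Hill curve of drug A, to floating-point resolution."""
    params = static_combination("JIMT-1", psi=1.0)
    conc = np.concatenate([[0.0], np.geomspace(1e-3, 10, 25)])
    combo = competitive_response(params, conc, np.zeros_like(conc))
    single = hill_response(params.drug_a, conc)
    np.testing.assert_allclose(combo, single, rtol=1e-12)
    assert competitive_response(params, 0.214, 0.0) == pytest.approx(53.64, abs=5e-3)


def test_both_drugs_at_ic50_full_imax():
    # x_a = x_b = 1 => inhibited fraction (1+1)/(1+1+1) = 2/3
    assert competitive_response(SIMPLE, 1.0, 2.0) == pytest.approx(100 / 3)


def test_invalid_psi_rejected():
    with pytest.raises(DomainError):
        CombinationParams(HillParams(100, 1, 1), HillParams(100, 1, 2), psi=0.0)


hill_st = st.builds(
    HillParams,
    r0=st.just(100.0),
    imax=st.floats(0.2, 1.0),
    ic50=st.floats(0.01, 100.0),
    gamma=st.floats(0.5, 3.0),
)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(a=hill_st, b=hill_st, ca=st.floats(0, 1e3), cb=st.floats(0, 1e3),
       psi=st.floats(0.1, 10))
def test_inhibited_fraction_bounded_by_max_imax(a, b, ca, cb, psi):
    params = CombinationParams(a, b, psi)
    r = competitive_response(params, ca, cb)
    floor = params.r0 * (1 - max(a.imax, b.imax))
    assert floor - 1e-9 <= r <= params.r0 + 1e-9


@settings(max_examples=40, deadline=None, derandomize=True)
@given(a=hill_st, b=hill_st, ca=st.floats(0.001, 1e3), cb=st.floats(0.001, 1e3),
       psi=st.floats(0.1, 5), factor=st.floats(1.0, 10))
def test_raising_psi_never_lowers_viability(a, b, ca, cb, psi, factor):
    lo = competitive_response(CombinationParams(a, b, psi), ca, cb)
    hi = competitive_response(CombinationParams(a, b, psi * factor), ca, cb)
    assert hi >= lo - 1e-9


# --------------------------------------------------------------- psi fitting
def _noise_free_grid(params):
    ca, cb = np.meshgrid(DOX_GRID, DEX_GRID, indexing="ij")
    return pd.DataFrame({
        "conc_dox_uM": ca.ravel(),
        "conc_dex_uM": cb.ravel(),
        "viability_pct": competitive_response(params, ca.ravel(), cb.ravel()),
    })


def test_fit_recovers_additivity_exactly():
    params = static_combination("JIMT-1", psi=1.0)
    res = InteractionModel(_noise_free_grid(params), params.drug_a, params.drug_b).fit()
    assert res.psi == pytest.approx(1.0, abs=1e-6)
    assert res.classification == "additive"


@pytest.mark.parametrize("cell_line", ["JIMT-1", "MDA-MB-468"])
def test_fit_recovers_published_interaction_estimates(cell_line):
    """Noise-free 6x6 grids generated at the published psi refit to the same
    value to two decimals (1.11 JIMT-1, 0.84 MDA-MB-468)."""
    params = static_combination(cell_line)
    res = InteractionModel(_noise_free_grid(params), params.drug_a, params.drug_b).fit()
    assert round(res.psi, 2) == STATIC_PSI[cell_line]


def test_fit_recovers_random_psi_scenarios():
    rng = np.random.default_rng(3)
    for _ in range(50):
        a = HillParams(100, rng.uniform(0.5, 1.0), np.exp(rng.uniform(-3, 0)))
        b = HillParams(100, rng.uniform(0.5, 1.0), np.exp(rng.uniform(1, 5)))
        psi = np.exp(rng.uniform(np.log(0.3), np.log(3.0)))
        truth = CombinationParams(a, b, psi)
        df = pd.DataFrame({
            "conc_dox_uM": np.repeat([a.ic50 / 3, a.ic50, 3 * a.ic50], 3),
            "conc_dex_uM": np.tile([b.ic50 / 3, b.ic50, 3 * b.ic50], 3),
        })
        df["viability_pct"] = competitive_response(
            truth, df.conc_dox_uM.to_numpy(), df.conc_dex_uM.to_numpy())
        res = InteractionModel(df, a, b).fit()
        assert abs(res.psi - psi) / psi < 1e-4


def test_fit_requires_combination_points():
    df = pd.DataFrame({
        "conc_dox_uM": [0.1, 0.2, 0.3, 0.4],
        "conc_dex_uM": [0.0] * 4,
        "viability_pct": [90, 80, 70, 60],
    })
    with pytest.raises(EstimationError):
        InteractionModel(df, SIMPLE.drug_a, SIMPLE.drug_b)


# ------------------------------------------------------------------ surface
def test_surface_single_point_and_margin_row():
    params = static_combination("JIMT-1", psi=1.0)
    assert additive_surface(params, [0.0], [0.0])[0, 0] == params.r0
    surf = additive_surface(params, DOX_GRID, [0.0])
    np.testing.assert_allclose(
        surf[:, 0], hill_response(params.drug_a, DOX_GRID), rtol=1e-12)


def test_surface_monotonicity():
    """With equal maximal inhibitions the surface is non-increasing along
    both axes; with unequal Imax it is guaranteed non-increasing only along
    the stronger drug's axis (competitive dilution by the weaker drug can
    raise viability at saturating concentrations of the stronger one)."""
    equal = CombinationParams(HillParams(100, 0.9, 0.2), HillParams(100, 0.9, 50.0))
    surf = additive_surface(equal, DOX_GRID, DEX_GRID)
    assert np.all(np.diff(surf, axis=0) <= 1e-9)
    assert np.all(np.diff(surf, axis=1) <= 1e-9)
    # JIMT-1: Imax_DOX (0.988) > Imax_DEX (0.74) -> monotone along DOX axis
    surf = additive_surface(static_combination("JIMT-1", psi=1.0), DOX_GRID, DEX_GRID)
    assert np.all(np.diff(surf, axis=0) <= 1e-9)


def test_surface_corner_matches_independent_hand_evaluation():
    """Corner (1 uM DOX, 200 uM DEX) of the JIMT-1 additive surface,
    cross-checked against a by-hand evaluation of the formula with plain
    scalar arithmetic (independent of the vectorized path)."""
    p = static_combination("JIMT-1", psi=1.0)
    x_a = (1.0 / 0.214) ** 1.0
    x_b = (200.0 / 97.5) ** 1.0
    expected = 106.0 * (1.0 - (0.988 * x_a + 0.74 * x_b) / (x_a + x_b + 1.0))
    surf = additive_surface(p, DOX_GRID, DEX_GRID)
    assert surf[-1, -1] == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(21.812, abs=5e-3)  # frozen golden value


def test_surface_frame_long_format():
    df = surface_frame(SIMPLE, [0.5, 1.0], [1.0, 2.0, 4.0])
    assert list(df.columns) == ["conc_dox_uM", "conc_dex_uM", "viability_pct"]
    assert len(df) == 6


# ----------------------------------------------------------- classification
def test_classification_on_surface_and_shifted():
    params = static_combination("JIMT-1", psi=1.0)
    df = _noise_free_grid(params)
    cls = classify_against_surface(df, params)
    assert cls.n_above == 0 and cls.n_total == 36
    shifted = df.assign(viability_pct=df.viability_pct * 1.05)
    assert classify_against_surface(shifted, params).n_above == 36


def test_antagonistic_data_sits_mostly_above_additive_surface():
    base = static_combination("JIMT-1", psi=1.0)
    design = DesignSpec(times=(72.0,), n_replicates=1, noise_cv=0.0)
    data = generate_static(design, CombinationParams(base.drug_a, base.drug_b, psi=2.0))
    combos = data.combinations()
    cls = classify_against_surface(combos, base)
    assert cls.n_above > cls.n_total / 2
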