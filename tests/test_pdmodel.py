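"""Dynamic cellular PD model: degradation forcing, ODE solution, limits."""

import numpy as np
import pytest
from scipy.integrate import quad

from combopd import (
    ConcentrationProfile,
    DegradationParams,
    DomainError,
    DrugKillParams,
    PDParams,
    medium_concentration,
    simulate_pd,
    simulate_pd_external,
)
from tests.conftest import rk4_oracle

T_GRID = np.arange(0.0, 97.0, 24.0)


# -------------------------------------------------------------- degradation
def test_medium_concentration_closed_form():
    assert medium_concentration(1.0, 0.022, 0.0) == 1.0
    half_life = np.log(2) / 0.022
    assert medium_concentration(1.0, 0.022, half_life) == pytest.approx(0.5, rel=1e-12)
    assert medium_concentration(200.0, 0.054, 24.0) == pytest.approx(
        200.0 * np.exp(-1.296), rel=1e-12)


def test_medium_concentration_rejects_negative_time():
    with pytest.raises(DomainError):
        medium_concentration(1.0, 0.022, -1.0)


# ---------------------------------------------------------------- dynamics
def test_control_matches_exponential_growth(jimt1_pd, deg):
    traj = simulate_pd(jimt1_pd, deg, 0.0, 0.0, T_GRID)
    expected = 100.0 * np.exp(0.0171 * T_GRID)
    np.testing.assert_allclose(traj["viability_pct"], expected, rtol=1e-6)
    assert traj["viability_pct"].iloc[-1] == pytest.approx(516.34, abs=0.01)


def test_zero_smax_equals_control(jimt1_pd, deg):
    disabled = PDParams(
        r0=jimt1_pd.r0, kg=jimt1_pd.kg,
        dox=DrugKillParams(0.0, jimt1_pd.dox.sc50, jimt1_pd.dox.tau),
        dex=DrugKillParams(0.0, jimt1_pd.dex.sc50, jimt1_pd.dex.tau),
        psi=jimt1_pd.psi)
    dosed = simulate_pd(disabled, deg, 1.0, 200.0, T_GRID)["viability_pct"]
    control = simulate_pd(disabled, deg, 0.0, 0.0, T_GRID)["viability_pct"]
    np.testing.assert_allclose(dosed, control, rtol=1e-9)


def test_combination_matches_independent_rk4_oracle(jimt1_pd, deg):
    """Adaptive solution vs a fixed-step RK4 oracle (dt = 0.01 h) that
    integrates viability as an explicit state: <= 0.1% everywhere."""
    traj = simulate_pd(jimt1_pd, deg, 1.0, 200.0, np.arange(0.0, 97.0, 1.0))
    ts, rs = rk4_oracle(jimt1_pd, deg, 1.0, 200.0, 96.0, dt=0.01)
    oracle = np.interp(traj["time_h"], ts, rs)
    np.testing.assert_allclose(traj["viability_pct"], oracle, rtol=1e-3)


def test_single_agent_matches_oracle(mda_pd, deg):
    traj = simulate_pd(mda_pd, deg, 0.5, 0.0, T_GRID)
    ts, rs = rk4_oracle(mda_pd, deg, 0.5, 0.0, 96.0, dt=0.01)
    np.testing.assert_allclose(
        traj["viability_pct"], np.interp(T_GRID, ts, rs), rtol=1e-3)


def test_short_transit_limit_converges_to_no_delay_model(deg):
    """As tau -> 0 the transit chain transmits the kill signal instantly and
    the trajectory approaches R0*exp(kg*t - int K dt) with K evaluated on
    the decaying concentration (reference via quadrature), <= 1% relative."""
    p = PDParams(r0=100.0, kg=0.02,
                 dox=DrugKillParams(smax=0.05, sc50=0.3, tau=1e-3),
                 dex=DrugKillParams(smax=0.01, sc50=20.0, tau=1e-3))
    c0 = 1.0
    traj = simulate_pd(p, deg, c0, 0.0, np.array([0.0, 12.0, 24.0, 48.0, 96.0]))

    def kill(t):
        c = c0 * np.exp(-deg.kdeg_dox * t)
        return p.dox.smax * c / (p.dox.sc50 + c)

    for t, r in zip(traj["time_h"], traj["viability_pct"]):
        integral = quad(kill, 0.0, t)[0]
        ref = 100.0 * np.exp(p.kg * t - integral)
        assert abs(r - ref) / ref < 0.01


def test_viability_strictly_positive(jimt1_pd, deg):
    strong = PDParams(r0=100.0, kg=0.0171,
                      dox=DrugKillParams(0.5, 0.01, 2.0),
                      dex=DrugKillParams(0.5, 1.0, 2.0))
    traj = simulate_pd(strong, deg, 10.0, 400.0, np.arange(0.0, 97.0, 8.0))
    assert np.all(traj["viability_pct"] > 0.0)


def test_antagonism_raises_viability_monotonically(jimt1_pd, deg):
    prev = None
    for psi in (0.5, 1.0, 2.0, 4.0):
        p = PDParams(r0=100.0, kg=jimt1_pd.kg, dox=jimt1_pd.dox,
                     dex=jimt1_pd.dex, psi=psi)
        v = simulate_pd(p, deg, 0.5, 100.0, T_GRID)["viability_pct"].to_numpy()
        if prev is not None:
            assert np.all(v >= prev - 1e-9)
        prev = v


def test_adding_dex_never_raises_viability_under_additivity(jimt1_pd, deg):
    """At psi = 1 the combination model coincides with the single-agent
    model for DOX, and kill rates are additive and non-negative, so a DEX
    co-exposure can only lower viability. (At psi > 1 the combination
    deliberately weakens the DOX kill, so the comparison can invert —
    antagonism enters solely through psi inflating the DOX potency.)"""
    additive = PDParams(r0=100.0, kg=jimt1_pd.kg, dox=jimt1_pd.dox,
                        dex=jimt1_pd.dex, psi=1.0)
    alone = simulate_pd(additive, deg, 0.5, 0.0, T_GRID)["viability_pct"]
    combo = simulate_pd(additive, deg, 0.5, 200.0, T_GRID)["viability_pct"]
    assert np.all(combo <= alone + 1e-9)


@pytest.mark.parametrize("bad_grid", [[0.0, 10.0, 5.0], [5.0, 10.0], [0.0, 0.0, 10.0]])
def test_invalid_time_grids_rejected(jimt1_pd, deg, bad_grid):
    with pytest.raises(DomainError):
        simulate_pd(jimt1_pd, deg, 1.0, 0.0, np.asarray(bad_grid))


# ------------------------------------------------------- external profiles
def test_zero_profiles_give_control_growth(jimt1_pd):
    traj = simulate_pd_external(jimt1_pd, None, None, T_GRID)
    np.testing.assert_allclose(
        traj["viability_pct"], 100.0 * np.exp(jimt1_pd.kg * T_GRID), rtol=1e-6)


def test_constant_profile_matches_negligible_degradation_limit(jimt1_pd):
    slow = DegradationParams(kdeg_dox=1e-12, kdeg_dex=1e-12)
    t = np.arange(0.0, 97.0, 4.0)
    const_dox = ConcentrationProfile(t, np.full_like(t, 0.5), site="medium")
    const_dex = ConcentrationProfile(t, np.full_like(t, 100.0), site="medium")
    a = simulate_pd_external(jimt1_pd, const_dox, const_dex, t)["viability_pct"]
    b = simulate_pd(jimt1_pd, slow, 0.5, 100.0, t)["viability_pct"]
    np.testing.assert_allclose(a, b, rtol=1e-3)


def test_exponential_profile_matches_rk4_oracle(jimt1_pd, deg):
    """Driving the model with a finely tabulated exponential profile must
    reproduce the closed-form-forced solution checked against the oracle."""
    t_fine = np.arange(0.0, 96.01, 0.05)
    prof = ConcentrationProfile(
        t_fine, 1.0 * np.exp(-deg.kdeg_dox * t_fine), site="tumor")
    traj = simulate_pd_external(jimt1_pd, prof, None, T_GRID)
    ts, rs = rk4_oracle(jimt1_pd, deg, 1.0, 0.0, 96.0, dt=0.01)
    np.testing.assert_allclose(
        traj["viability_pct"], np.interp(T_GRID, ts, rs), rtol=1e-3)


def test_profile_must_cover_grid(jimt1_pd):
    short = ConcentrationProfile(np.array([0.0, 48.0]), np.array([1.0, 0.5]))
    with pytest.raises(DomainError):
        simulate_pd_external(jimt1_pd, short, None, T_GRID)
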