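"""Competitive interaction model and 3D response-surface analysis.

Joint static effects of two inhibitory drugs A and B on % viability are
modeled with a competitive interaction extension of the Hill model:

    x_A = (C_A / (psi * IC50_A))^gamma_A
    x_B = (C_B / (psi * IC50_B))^gamma_B
    R   = R0 * (1 - (Imax_A * x_A + Imax_B * x_B) / (x_A + x_B + 1))

psi is the interaction term: psi = 1 additive, psi < 1 synergistic
(joint potency higher than additive), psi > 1 antagonistic. With C_B = 0 and
psi = 1 the expression reduces algebraically to the single-agent Hill model
for drug A. psi multiplies both IC50s by default; ``psi_on`` restricts it to
one drug's potency for sensitivity analysis.

The workflow mirrors the static analysis of a checkerboard combination
experiment: fit each single agent with :class:`~combopd.hill.HillModel`,
freeze those parameters, then estimate psi from the combination grid with
:class:`InteractionModel`; generate the additive (psi=1) surface and classify
observed points as above (antagonistic direction) or at/below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, EstimationError
from .fitutil import FitReport, least_squares_fit
from .hill import HillParams, hill_response

__all__ = [
    "CombinationParams",
    "competitive_response",
    "additive_surface",
    "SurfaceClassification",
    "classify_against_surface",
    "InteractionModel",
    "InteractionResults",
]


@dataclass(frozen=True)
class CombinationParams:
    """Paired single-agent Hill parameters plus the interaction term psi.

    The baseline of the combination surface is ``drug_a.r0`` (the two
    single-agent fits may estimate slightly different baselines; the surface
    needs one). ``psi_on`` selects which potencies psi multiplies:
    'both' (default), 'a', or 'b'.
    """

    drug_a: HillParams
    drug_b: HillParams
    psi: float = 1.0
    psi_on: str = "both"

    def __post_init__(self):
        if not self.psi > 0:
            raise DomainError(f"psi must be > 0, got {self.psi}")
        if self.psi_on not in ("both", "a", "b"):
            raise DomainError(f"psi_on must be 'both', 'a' or 'b', got {self.psi_on!r}")

    @property
    def r0(self) -> float:
        return self.drug_a.r0

    def to_dict(self) -> dict:
        return {
            "drug_a": self.drug_a.to_dict(),
            "drug_b": self.drug_b.to_dict(),
            "psi": self.psi,
            "psi_on": self.psi_on,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CombinationParams":
        return cls(
            HillParams.from_dict(d["drug_a"]),
            HillParams.from_dict(d["drug_b"]),
            float(d.get("psi", 1.0)),
            d.get("psi_on", "both"),
        )


def competitive_response(params: CombinationParams, conc_a, conc_b):
    """Viability (%) of the combination at (conc_a, conc_b) uM; vectorized.

    Reduces exactly to the single-agent Hill curve of drug A when conc_b = 0
    (and symmetrically for drug B up to the shared baseline): psi describes
    the joint potency shift, so it engages only where both drugs are dosed.
    """
    conc_a = np.asarray(conc_a, dtype=float)
    conc_b = np.asarray(conc_b, dtype=float)
    if np.any(conc_a < 0) or np.any(conc_b < 0):
        raise DomainError("concentrations must be >= 0")
    a, b = params.drug_a, params.drug_b
    # the interaction term modifies potency only where both drugs are
    # present, so margins reduce to the single-agent Hill curves for any psi
    both = (conc_a > 0) & (conc_b > 0)
    psi_a = np.where(both, params.psi if params.psi_on in ("both", "a") else 1.0, 1.0)
    psi_b = np.where(both, params.psi if params.psi_on in ("both", "b") else 1.0, 1.0)
    x_a = np.power(conc_a / (psi_a * a.ic50), a.gamma)
    x_b = np.power(conc_b / (psi_b * b.ic50), b.gamma)
    frac = (a.imax * x_a + b.imax * x_b) / (x_a + x_b + 1.0)
    out = params.r0 * (1.0 - frac)
    return out if out.ndim else float(out)


def additive_surface(
    params: CombinationParams, grid_a: Sequence[float], grid_b: Sequence[float]
) -> np.ndarray:
    """Additive-interaction (psi=1) response surface over a concentration grid.

    Returns a len(grid_a) x len(grid_b) matrix with entry [i, j] the
    predicted viability at (grid_a[i], grid_b[j]); non-increasing along both
    axes.
    """
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    if grid_a.size == 0 or grid_b.size == 0:
        raise DomainError("grids must be non-empty")
    additive = replace(params, psi=1.0)
    return competitive_response(additive, grid_a[:, None], grid_b[None, :])


@dataclass
class SurfaceClassification:
    """Observed combination points relative to the additive surface.

    Points strictly above the surface lie in the antagonistic direction
    (higher viability than additivity predicts); points at or below in the
    additive/synergistic direction.
    """

    n_above: int
    n_below_or_on: int
    residuals: np.ndarray = field(repr=False)

    @property
    def n_total(self) -> int:
        return self.n_above + self.n_below_or_on


def classify_against_surface(data, params: CombinationParams) -> SurfaceClassification:
    """Signed residuals of observations vs the additive (psi=1) prediction.

    ``data`` is a ViabilityDataset or DataFrame with conc_dox_uM /
    conc_dex_uM / viability_pct columns; the surface is evaluated pointwise
    at each observation's own concentrations (no interpolation).
    """
    df = data.frame if hasattr(data, "frame") else pd.DataFrame(data)
    additive = replace(params, psi=1.0)
    pred = competitive_response(
        additive, df["conc_dox_uM"].to_numpy(), df["conc_dex_uM"].to_numpy()
    )
    resid = df["viability_pct"].to_numpy() - pred
    n_above = int(np.sum(resid > 0))
    return SurfaceClassification(n_above, resid.size - n_above, resid)


class InteractionModel:
    """Estimate the interaction term psi from combination viability data.

    Single-agent Hill parameters are supplied fixed (from their own fits);
    psi is the single free parameter. Grid margins (records where one drug's
    concentration is zero) are included by default; their predictions do not
    depend on psi, so they contribute residual-variance information only and
    can be dropped with ``include_margins=False``.
    """

    def __init__(
        self,
        data,
        drug_a: HillParams,
        drug_b: HillParams,
        *,
        psi_on: str = "both",
        include_margins: bool = True,
        additive_band: float = 0.05,
    ):
        df = data.frame if hasattr(data, "frame") else pd.DataFrame(data)
        ca = df["conc_dox_uM"].to_numpy(dtype=float)
        cb = df["conc_dex_uM"].to_numpy(dtype=float)
        y = df["viability_pct"].to_numpy(dtype=float)
        keep = (ca > 0) & (cb > 0) if not include_margins else (ca > 0) | (cb > 0)
        if int(np.sum((ca > 0) & (cb > 0))) < 4:
            raise EstimationError("need >= 4 combination points with both drugs dosed")
        self.conc_a, self.conc_b, self.response = ca[keep], cb[keep], y[keep]
        self.drug_a, self.drug_b = drug_a, drug_b
        self.psi_on = psi_on
        self.additive_band = float(additive_band)

    def fit(self, init_psi: float = 1.0, *, loss: str = "ols") -> "InteractionResults":
        def predict(theta: np.ndarray) -> np.ndarray:
            p = CombinationParams(self.drug_a, self.drug_b, float(theta[0]), self.psi_on)
            return competitive_response(p, self.conc_a, self.conc_b)

        weights = None
        if loss == "proportional":
            weights = 1.0 / np.clip(predict(np.array([init_psi])), 1e-6, None)
        out = least_squares_fit(predict, self.response, np.array([init_psi]), weights=weights)
        psi = float(out["x"][0])
        report = FitReport(
            estimates={"psi": psi},
            rse_pct={"psi": float(out["rse_pct"][0])},
            objective=out["objective"],
            converged=out["converged"],
            n_obs=self.response.size,
            fixed=("drug_a", "drug_b"),
            message=out["message"],
        )
        return InteractionResults(self, report)


class InteractionResults:
    """psi estimate with its interaction-class label."""

    def __init__(self, model: InteractionModel, report: FitReport):
        self.model = model
        self._report = report
        self.psi = report.estimates["psi"]
        self.rse_pct = report.rse_pct
        self.objective = report.objective
        self.converged = report.converged
        self.n_obs = report.n_obs
        self.params = CombinationParams(model.drug_a, model.drug_b, self.psi, model.psi_on)

    @property
    def classification(self) -> str:
        """'additive' within +/-band of 1, else 'antagonistic' / 'synergistic'."""
        band = self.model.additive_band
        if abs(self.psi - 1.0) <= band:
            return "additive"
        return "antagonistic" if self.psi > 1.0 else "synergistic"

    def predict(self, conc_a, conc_b):
        return competitive_response(self.params, conc_a, conc_b)

    def summary(self) -> str:
        lines = self._report.summary_lines("Competitive interaction model fit")
        lines.append(f"interaction: {self.classification} "
                     f"(psi > 1 antagonistic, < 1 synergistic, band +/-{self.model.additive_band})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "psi": self.psi,
            "rse_pct": self.rse_pct,
            "classification": self.classification,
            "objective": self.objective,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def surface_frame(
    params: CombinationParams, grid_a: Sequence[float], grid_b: Sequence[float]
) -> pd.DataFrame:
    """Long-format (conc_dox_uM, conc_dex_uM, viability_pct) additive surface."""
    mat = additive_surface(params, grid_a, grid_b)
    ga, gb = np.meshgrid(grid_a, grid_b, indexing="ij")
    return pd.DataFrame({
        "conc_dox_uM": ga.ravel(),
        "conc_dex_uM": gb.ravel(),
        "viability_pct": mat.ravel(),
    })
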