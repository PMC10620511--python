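"""Inhibitory Hill (Emax) model for static concentration-response data.

The single-agent model for % cell viability R at drug concentration C is

    R(C) = R0 * (1 - Imax * C^gamma / (IC50^gamma + C^gamma))

with R0 the baseline viability of untreated cells (%), Imax the maximal
fractional inhibition (0..1), IC50 the half-maximal inhibitory concentration
(uM) and gamma a Hill exponent. The default analysis pipeline fixes gamma=1,
which keeps the single-agent model consistent with the competitive
interaction model used for combinations (see :mod:`combopd.interaction`);
gamma can be freed on request.

Usage follows the statsmodels pattern::

    model = HillModel(conc_uM, viability_pct)
    res = model.fit(fixed={"r0": 100.0})
    print(res.summary())
    res.predict([0.01, 0.1, 1.0])
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, EstimationError
from .fitutil import FitReport, least_squares_fit

__all__ = ["HillParams", "hill_response", "HillModel", "HillResults"]

_PARAM_ORDER = ("r0", "imax", "ic50", "gamma")


@dataclass(frozen=True)
class HillParams:
    """Single-agent inhibitory Hill parameters.

    r0 : baseline viability (%), > 0
    imax : maximal fractional inhibition, in [0, 1]
    ic50 : half-maximal inhibitory concentration (uM), > 0
    gamma : Hill exponent, > 0 (default 1)
    """

    r0: float
    imax: float
    ic50: float
    gamma: float = 1.0

    def __post_init__(self):
        if not self.r0 > 0:
            raise DomainError(f"r0 must be > 0, got {self.r0}")
        if not 0.0 <= self.imax <= 1.0:
            raise DomainError(f"imax must be in [0, 1], got {self.imax}")
        if not self.ic50 > 0:
            raise DomainError(f"ic50 must be > 0, got {self.ic50}")
        if not self.gamma > 0:
            raise DomainError(f"gamma must be > 0, got {self.gamma}")

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _PARAM_ORDER}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "HillParams":
        return cls(**{k: float(d[k]) for k in _PARAM_ORDER if k in d})


def hill_response(params: HillParams, conc):
    """Viability (%) at concentration ``conc`` (uM); vectorized over conc.

    Monotone non-increasing in conc, bounded in [r0*(1-imax), r0], and equal
    to r0 exactly at conc=0. Negative concentrations are rejected.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise DomainError("concentration must be >= 0")
    cg = np.power(conc, params.gamma)
    frac = params.imax * cg / (params.ic50**params.gamma + cg)
    out = params.r0 * (1.0 - frac)
    return out if out.ndim else float(out)


class HillModel:
    """Inhibitory Hill model bound to one drug's static viability data.

    Parameters
    ----------
    conc : concentrations in uM (include 0 / vehicle control)
    response : % viability observations, same length
    """

    def __init__(self, conc: Sequence[float], response: Sequence[float]):
        conc = np.asarray(conc, dtype=float)
        response = np.asarray(response, dtype=float)
        if conc.shape != response.shape or conc.ndim != 1:
            raise DataError("conc and response must be 1-D arrays of equal length")
        if np.any(conc < 0):
            raise DomainError("concentration must be >= 0")
        if np.unique(conc).size < 4:
            raise DataError("need >= 4 distinct concentrations to fit a Hill curve")
        self.conc = conc
        self.response = response

    @classmethod
    def from_dataset(cls, data, drug: str, cell_line: str | None = None,
                     time_h: float | None = None) -> "HillModel":
        """Build from a :class:`~combopd.datasets.ViabilityDataset`.

        Selects records where only ``drug`` ('dox' or 'dex') is dosed, plus
        the shared (0, 0) controls, at one time point.
        """
        df = data.frame if hasattr(data, "frame") else pd.DataFrame(data)
        if cell_line is not None:
            df = df[df["cell_line"] == cell_line]
        if time_h is not None:
            df = df[np.isclose(df["time_h"], time_h)]
        elif df["time_h"].nunique() > 1:
            raise DataError("multiple time points present; pass time_h explicitly")
        this, other = (("conc_dox_uM", "conc_dex_uM") if drug.lower() == "dox"
                       else ("conc_dex_uM", "conc_dox_uM"))
        df = df[df[other] == 0.0]
        if df.empty:
            raise DataError(f"no single-agent records for drug '{drug}'")
        return cls(df[this].to_numpy(), df["viability_pct"].to_numpy())

    def _initial(self, fixed: Mapping[str, float]) -> HillParams:
        """Heuristic start: r0 from controls, imax from the response range,
        ic50 at the geometric mean of tested nonzero concentrations."""
        controls = self.response[self.conc == 0]
        r0 = float(fixed.get("r0", controls.mean() if controls.size else self.response.max()))
        rng_max, rng_min = float(self.response.max()), float(self.response.min())
        imax = float(fixed.get("imax", np.clip(1.0 - rng_min / max(rng_max, 1e-9), 0.05, 0.99)))
        nz = self.conc[self.conc > 0]
        ic50 = float(fixed.get("ic50", np.exp(np.mean(np.log(nz)))))
        gamma = float(fixed.get("gamma", 1.0))
        return HillParams(max(r0, 1e-6), imax, ic50, gamma)

    def fit(
        self,
        fixed: Mapping[str, float] | None = None,
        init: HillParams | None = None,
        *,
        fit_gamma: bool = False,
        n_starts: int = 5,
        seed: int = 0,
        loss: str = "ols",
    ) -> "HillResults":
        """Fit free Hill parameters by (multi-start) least squares.

        ``fixed`` maps parameter names to values held constant (Table-style
        conventions such as fixing r0=100 are expressed this way). gamma is
        fixed at 1 unless ``fit_gamma=True`` or gamma appears in ``fixed``
        with another value. ``loss='proportional'`` weights residuals by the
        reciprocal model prediction (proportional-error ML up to a constant).
        """
        fixed = dict(fixed or {})
        if np.ptp(self.response) == 0:
            raise EstimationError("no concentration effect: all responses identical")
        start = init if init is not None else self._initial(fixed)

        free = [p for p in _PARAM_ORDER if p not in fixed]
        if not fit_gamma and "gamma" not in fixed:
            fixed["gamma"] = start.gamma
            free.remove("gamma")
        if not free:
            raise EstimationError("all parameters fixed; nothing to estimate")

        base = {**start.to_dict(), **fixed}

        def predict(theta: np.ndarray) -> np.ndarray:
            p = dict(base)
            p.update(zip(free, theta))
            # imax is optimized in log space; clip into the valid domain
            p["imax"] = min(p["imax"], 1.0)
            return hill_response(HillParams(**p), self.conc)

        x0 = np.array([base[p] for p in free], dtype=float)
        weights = None
        if loss == "proportional":
            weights = 1.0 / np.clip(hill_response(HillParams(**base), self.conc), 1e-6, None)
        elif loss != "ols":
            raise DomainError(f"unknown loss '{loss}'")

        # multi-start over IC50 only would lose the joint perturbation; the
        # shared helper perturbs all free parameters log-uniformly instead,
        # which covers the log-spaced IC50 starts and more.
        out = least_squares_fit(
            predict, self.response, x0,
            n_starts=n_starts, seed=seed, weights=weights,
        )
        estimates = dict(base)
        estimates.update(zip(free, out["x"]))
        estimates["imax"] = min(estimates["imax"], 1.0)
        report = FitReport(
            estimates={k: float(estimates[k]) for k in _PARAM_ORDER},
            rse_pct=dict(zip(free, (float(r) for r in out["rse_pct"]))),
            objective=out["objective"],
            converged=out["converged"],
            n_obs=self.response.size,
            fixed=tuple(fixed),
            message=out["message"],
            n_starts=n_starts,
        )
        return HillResults(self, report)


class HillResults:
    """Results of a :class:`HillModel` fit."""

    def __init__(self, model: HillModel, report: FitReport):
        self.model = model
        self._report = report
        self.params = HillParams.from_dict(report.estimates)
        self.rse_pct = report.rse_pct
        self.objective = report.objective
        self.converged = report.converged
        self.n_obs = report.n_obs
        self.fixed = report.fixed

    def predict(self, conc) -> np.ndarray:
        return hill_response(self.params, conc)

    def curve(self, n: int = 50) -> pd.DataFrame:
        """Fitted curve on a log grid spanning the tested nonzero range."""
        nz = self.model.conc[self.model.conc > 0]
        grid = np.geomspace(nz.min(), nz.max(), n)
        return pd.DataFrame({"conc_uM": grid, "viability_pct": self.predict(grid)})

    def summary(self) -> str:
        return "\n".join(self._report.summary_lines("Inhibitory Hill model fit"))

    def to_dict(self) -> dict:
        return {
            "estimates": self._report.estimates,
            "rse_pct": self.rse_pct,
            "objective": self.objective,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "fixed": list(self.fixed),
        }
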