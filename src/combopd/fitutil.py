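"""Shared nonlinear least-squares machinery.

All fits in the package go through :func:`least_squares_fit`: ordinary (or
proportional-error weighted) least squares on % viability, optional
log-transform of positive parameters, multi-start initialisation, and
asymptotic %RSE from the Gauss-Newton approximation of the Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitReport", "least_squares_fit", "rse_from_jacobian"]


@dataclass
class FitReport:
    """Generic fit outcome shared by all Results classes.

    estimates map free *and* fixed parameters to their values; ``rse_pct``
    has entries only for free parameters (a fixed parameter has no sampling
    uncertainty, so its RSE is reported as absent, never 0).
    """

    estimates: dict[str, float]
    rse_pct: dict[str, float]
    objective: float
    converged: bool
    n_obs: int
    fixed: tuple[str, ...] = ()
    message: str = ""
    n_starts: int = 1
    extra: dict = field(default_factory=dict)

    def summary_lines(self, title: str) -> list[str]:
        width = max(len(k) for k in self.estimates) + 2
        lines = [title, "=" * len(title)]
        lines.append(f"{'parameter':<{width}}{'estimate':>12}  {'%RSE':>8}")
        for name, value in self.estimates.items():
            if name in self.fixed:
                rse = "(fixed)"
            elif name in self.rse_pct:
                rse = f"{self.rse_pct[name]:.3g}"
            else:
                rse = "-"
            lines.append(f"{name:<{width}}{value:>12.5g}  {rse:>8}")
        lines.append(
            f"objective (SSR): {self.objective:.6g}   n_obs: {self.n_obs}   "
            f"converged: {self.converged}"
        )
        return lines


def rse_from_jacobian(
    jac: np.ndarray, residuals: np.ndarray, estimates: np.ndarray, log_scale: bool
) -> np.ndarray:
    """%RSE per free parameter from the asymptotic covariance.

    Covariance = (J'J)^-1 * s2 with s2 the residual variance on n-p dof.
    When the optimisation ran in log space the SE of log(theta) *is* the
    relative SE of theta (delta method), so %RSE = 100*SE_log directly.
    """
    n, p = jac.shape
    if n <= p:
        return np.full(p, np.nan)
    s2 = float(residuals @ residuals) / (n - p)
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    if log_scale:
        return 100.0 * se
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(estimates != 0, 100.0 * se / np.abs(estimates), np.nan)


def least_squares_fit(
    predict: Callable[[np.ndarray], np.ndarray],
    observed: np.ndarray,
    x0: np.ndarray,
    *,
    log_scale: bool = True,
    bounds: tuple | None = None,
    weights: np.ndarray | None = None,
    n_starts: int = 1,
    start_spread: float = 3.0,
    seed: int | None = None,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
) -> dict:
    """Run (multi-start) least squares of ``predict(theta)`` against ``observed``.

    Parameters are optimised in log space by default (all model parameters
    here are positive rates/concentrations). Multi-start perturbs ``x0``
    log-uniformly within a factor ``start_spread`` and keeps the best
    objective; the first start is always the unperturbed ``x0``.
    """
    observed = np.asarray(observed, dtype=float)
    w = np.ones_like(observed) if weights is None else np.asarray(weights, float)

    if log_scale:
        z0 = np.log(x0)
        decode = np.exp
        lb, ub = -np.inf, np.inf
    else:
        z0 = np.asarray(x0, dtype=float)
        decode = lambda z: z  # noqa: E731
        lb, ub = (bounds if bounds is not None else (-np.inf, np.inf))

    def residuals(z: np.ndarray) -> np.ndarray:
        pred = predict(decode(z))
        return w * (pred - observed)

    rng = np.random.default_rng(seed)
    starts = [z0]
    for _ in range(n_starts - 1):
        if log_scale:
            starts.append(z0 + rng.uniform(-np.log(start_spread), np.log(start_spread), z0.size))
        else:
            starts.append(z0 * rng.uniform(1.0 / start_spread, start_spread, z0.size))

    best = None
    for z_start in starts:
        try:
            sol = least_squares(
                residuals, z_start, bounds=(lb, ub), xtol=xtol, ftol=ftol, gtol=1e-12
            )
        except Exception:  # numerical blow-up from a bad start: skip it
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return {
            "x": np.asarray(x0, float),
            "objective": np.inf,
            "converged": False,
            "rse_pct": np.full(len(np.atleast_1d(x0)), np.nan),
            "message": "all optimizer starts failed",
        }

    theta = decode(best.x)
    res = best.fun
    rse = rse_from_jacobian(best.jac, res, theta, log_scale)
    return {
        "x": theta,
        "objective": float(res @ res),
        "converged": bool(best.status > 0),
        "rse_pct": rse,
        "message": best.message,
    }
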