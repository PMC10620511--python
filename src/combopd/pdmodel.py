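"""Cellular-level pharmacodynamic model of drug-induced cell kill.

Untreated cells grow exponentially, dR/dt = kg * R, with R the % viability
signal of the assay. Each drug stimulates cell death through a
capacity-limited (Hill) kill function of its concentration,

    K_drug(t) = Smax * C(t) / (SC50_eff + C(t)),

whose effect is delayed by a chain of three transit compartments with mean
transit time tau:

    dK1/dt = (K - K1)/tau,  dK2/dt = (K1 - K2)/tau,  dK3/dt = (K2 - K3)/tau,

and the terminal signals act additively on viability,

    dR/dt = kg*R - (K3_dox + K3_dex) * R.

For combinations an interaction parameter psi inflates the doxorubicin
potency, SC50_eff = SC50_dox * psi (psi = 1 additive, > 1 antagonistic,
< 1 synergistic); the dexrazoxane kill function is unmodified. A single-agent
simulation is the psi = 1 special case, so one code path serves both. The
``psi_on`` flag allows the symmetric placement (both SC50s) for exploration.

In vitro the drugs degrade in culture medium with first-order kinetics,
C(t) = C0 * exp(-kdeg * t); for translation the same ODE system can instead
be driven by arbitrary concentration profiles (e.g. simulated tumor-site PK).

Because the kill signals enter multiplicatively on R, the system is solved
for the transit chain plus the cumulative kill integral J(t) = int K3_tot dt
and viability recovered as R(t) = R0 * exp(kg*t - J(t)), which is exact,
keeps R strictly positive, and removes R's scale from the error control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DomainError, SolverError
from .profiles import ConcentrationProfile

__all__ = [
    "DegradationParams",
    "DrugKillParams",
    "PDParams",
    "medium_concentration",
    "simulate_pd",
    "simulate_pd_external",
]


@dataclass(frozen=True)
class DegradationParams:
    """First-order degradation rate constants in culture medium (1/h)."""

    kdeg_dox: float
    kdeg_dex: float

    def __post_init__(self):
        if not (self.kdeg_dox > 0 and self.kdeg_dex > 0):
            raise DomainError("degradation rate constants must be > 0")


@dataclass(frozen=True)
class DrugKillParams:
    """Per-drug kill parameters: Smax (1/h), SC50 (uM), tau (h)."""

    smax: float
    sc50: float
    tau: float

    def __post_init__(self):
        if not (self.smax >= 0 and self.sc50 > 0 and self.tau > 0):
            raise DomainError("require smax >= 0, sc50 > 0, tau > 0")

    def to_dict(self):
        return {"smax": self.smax, "sc50": self.sc50, "tau": self.tau}


@dataclass(frozen=True)
class PDParams:
    """Full dynamic model parameter set.

    r0 : baseline viability (%)
    kg : first-order growth rate (1/h)
    dox, dex : kill parameters per drug
    psi : interaction parameter on the DOX potency (1 = additive)
    psi_on : 'dox' (default) or 'both' for symmetric placement
    """

    r0: float
    kg: float
    dox: DrugKillParams
    dex: DrugKillParams
    psi: float = 1.0
    psi_on: str = "dox"

    def __post_init__(self):
        if not self.r0 > 0:
            raise DomainError("r0 must be > 0")
        if not self.kg > 0:
            raise DomainError("kg must be > 0")
        if not self.psi > 0:
            raise DomainError("psi must be > 0")
        if self.psi_on not in ("dox", "both"):
            raise DomainError("psi_on must be 'dox' or 'both'")

    def to_dict(self) -> dict:
        return {
            "r0": self.r0, "kg": self.kg,
            "dox": self.dox.to_dict(), "dex": self.dex.to_dict(),
            "psi": self.psi, "psi_on": self.psi_on,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PDParams":
        return cls(
            float(d["r0"]), float(d["kg"]),
            DrugKillParams(**{k: float(v) for k, v in d["dox"].items()}),
            DrugKillParams(**{k: float(v) for k, v in d["dex"].items()}),
            float(d.get("psi", 1.0)), d.get("psi_on", "dox"),
        )


def medium_concentration(c0: float, kdeg: float, t):
    """Drug concentration in culture medium: c0 * exp(-kdeg * t), exact."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    if c0 < 0:
        raise DomainError("c0 must be >= 0")
    out = c0 * np.exp(-kdeg * t)
    return out if out.ndim else float(out)


def _check_grid(t_grid) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise DomainError("t_grid must be a 1-D array")
    if t[0] != 0:
        raise DomainError("t_grid must start at 0 (initial condition time)")
    if np.any(np.diff(t) <= 0):
        raise DomainError("t_grid must be strictly increasing")
    return t


def _solve(params: PDParams, conc_dox, conc_dex, t_grid, rtol, atol, max_step,
           combination: bool):
    """Integrate the transit chains + cumulative kill; return trajectory frame.

    conc_dox / conc_dex are callables t -> uM (vector-safe for output only;
    the RHS calls them with scalars). ``combination`` gates psi: the
    interaction term modifies the DOX potency only when both drugs are
    present, so single-agent simulations degenerate to the psi-free model
    and one code path serves both.
    """
    t = _check_grid(t_grid)
    psi = params.psi if combination else 1.0
    sc50_dox_eff = params.dox.sc50 * psi
    sc50_dex_eff = params.dex.sc50 * (psi if params.psi_on == "both" else 1.0)
    inv_tau_dox = 1.0 / params.dox.tau
    inv_tau_dex = 1.0 / params.dex.tau
    smax_dox, smax_dex = params.dox.smax, params.dex.smax

    def rhs(ti, y):
        k1d, k2d, k3d, k1x, k2x, k3x, _ = y
        cd = conc_dox(ti)
        cx = conc_dex(ti)
        kd = smax_dox * cd / (sc50_dox_eff + cd) if cd > 0 else 0.0
        kx = smax_dex * cx / (sc50_dex_eff + cx) if cx > 0 else 0.0
        return (
            inv_tau_dox * (kd - k1d),
            inv_tau_dox * (k1d - k2d),
            inv_tau_dox * (k2d - k3d),
            inv_tau_dex * (kx - k1x),
            inv_tau_dex * (k1x - k2x),
            inv_tau_dex * (k2x - k3x),
            k3d + k3x,
        )

    if t.size == 1:  # only t=0 requested
        ys = np.zeros((7, 1))
    else:
        sol = solve_ivp(
            rhs, (t[0], t[-1]), np.zeros(7), method="LSODA",
            t_eval=t, rtol=rtol, atol=atol, max_step=max_step,
        )
        if not sol.success:
            raise SolverError(f"PD integration failed: {sol.message}")
        ys = sol.y
    j = ys[6]
    viability = params.r0 * np.exp(params.kg * t - j)
    return pd.DataFrame({
        "time_h": t,
        "viability_pct": viability,
        "conc_dox_uM": np.asarray(conc_dox(t), dtype=float),
        "conc_dex_uM": np.asarray(conc_dex(t), dtype=float),
    })


def simulate_pd(
    params: PDParams,
    deg: DegradationParams,
    c0_dox: float,
    c0_dex: float,
    t_grid: Sequence[float],
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Simulate viability under in vitro exposure with medium degradation.

    c0_dox / c0_dex are the initial medium concentrations (uM); 0 leaves the
    corresponding kill chain silent. Returns a frame with time_h,
    viability_pct and the driving concentrations.
    """
    if c0_dox < 0 or c0_dex < 0:
        raise DomainError("initial concentrations must be >= 0")

    def cd(ti):
        return c0_dox * np.exp(-deg.kdeg_dox * ti)

    def cx(ti):
        return c0_dex * np.exp(-deg.kdeg_dex * ti)

    return _solve(params, cd, cx, t_grid, rtol, atol, np.inf,
                  combination=(c0_dox > 0 and c0_dex > 0))


def simulate_pd_external(
    params: PDParams,
    conc_dox: ConcentrationProfile | None,
    conc_dex: ConcentrationProfile | None,
    t_grid: Sequence[float],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Simulate viability driven by externally supplied concentration profiles.

    Profiles are interpolated linearly in time and must cover the simulation
    grid; ``None`` means the drug is absent. Used for translation, where
    simulated tumor-site PK drives the cellular model.
    """
    t = _check_grid(t_grid)
    for prof in (conc_dox, conc_dex):
        if prof is not None and prof.times[-1] < t[-1] - 1e-9:
            raise DomainError(
                f"profile for site '{prof.site}' ends at {prof.times[-1]} h "
                f"but the grid extends to {t[-1]} h"
            )
    zero = lambda ti: np.zeros_like(np.asarray(ti, dtype=float)) if np.ndim(ti) else 0.0  # noqa: E731
    cd = conc_dox if conc_dox is not None else zero
    cx = conc_dex if conc_dex is not None else zero
    combination = (
        conc_dox is not None and np.any(conc_dox.concentrations > 0)
        and conc_dex is not None and np.any(conc_dex.concentrations > 0)
    )
    # cap the step so the solver cannot leap over profile kinks (infusion ends)
    max_step = max((t[-1] - t[0]) / 100.0, 1.0)
    return _solve(params, cd, cx, t, rtol, atol, max_step, combination=combination)
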