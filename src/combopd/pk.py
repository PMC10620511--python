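"""Linear mammillary PK models and multi-cycle infusion regimens.

Doxorubicin plasma kinetics are described with a three-compartment model and
dexrazoxane with a two-compartment model, parameterized per body-surface
area: central volume V1 (L/m2), clearance CL (L/h/m2) and inter-compartmental
clearance / peripheral volume pairs (Q2, V2[, Q3, V3]). Dosing events are
zero-order infusions (duration 0 = bolus) of dose D (mg/m2), repeated over
Q3W-style cycles.

The system is linear, so it is solved exactly: within each interval of
constant infusion rate the amounts follow x(t) = xp + V e^{L t} V^{-1}(x0-xp)
with (L, V) the eigendecomposition of the rate matrix and xp the steady
input-balance solution. Superposition and dose-proportionality therefore
hold to machine precision, which the tests assert.

Concentrations are reported in uM: (mg/L) / MW(g/mol) * 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError
from .profiles import ConcentrationProfile

__all__ = ["PKParams", "DoseEvent", "Regimen", "simulate_pk"]

# molecular weights (g/mol) for mg -> umol conversion
MW_DOX = 543.5
MW_DEX = 268.3


@dataclass(frozen=True)
class PKParams:
    """Compartmental PK parameter set (per m2 of body surface area).

    model : '3cpt' or '2cpt'
    v1 : central volume (L/m2);  cl : clearance (L/h/m2)
    q2, v2 (and q3, v3 for 3cpt) : inter-compartmental clearance (L/h/m2)
        and peripheral volume (L/m2); a pair with q = 0 degenerates that
        compartment away (useful for closed-form checks).
    mw : molecular weight (g/mol) for the mass-to-molar conversion.
    """

    model: str
    v1: float
    cl: float
    mw: float
    q2: float = 0.0
    v2: float = 1.0
    q3: float = 0.0
    v3: float = 1.0

    def __post_init__(self):
        if self.model not in ("2cpt", "3cpt"):
            raise DomainError(f"model must be '2cpt' or '3cpt', got {self.model!r}")
        if not (self.v1 > 0 and self.cl > 0 and self.mw > 0):
            raise DomainError("v1, cl and mw must be > 0")
        if self.q2 < 0 or self.q3 < 0 or self.v2 <= 0 or self.v3 <= 0:
            raise DomainError("inter-compartmental clearances must be >= 0, volumes > 0")
        if self.model == "2cpt" and self.q3 != 0:
            raise DomainError("q3 must be 0 for a 2-compartment model")

    def rate_matrix(self) -> np.ndarray:
        """First-order rate matrix on amounts, zero-Q peripherals pruned."""
        pairs = [(self.q2, self.v2)]
        if self.model == "3cpt":
            pairs.append((self.q3, self.v3))
        pairs = [(q, v) for q, v in pairs if q > 0]
        n = 1 + len(pairs)
        a = np.zeros((n, n))
        a[0, 0] = -self.cl / self.v1
        for i, (q, v) in enumerate(pairs, start=1):
            a[0, 0] -= q / self.v1
            a[0, i] = q / v
            a[i, 0] = q / self.v1
            a[i, i] = -q / v
        return a


@dataclass(frozen=True)
class DoseEvent:
    """One administration: dose (mg/m2) infused over ``duration`` h starting
    at ``start`` h within the cycle; duration 0 means an instantaneous bolus."""

    drug: str
    dose: float
    start: float
    duration: float = 0.0

    def __post_init__(self):
        if not self.dose > 0:
            raise DomainError("dose must be > 0")
        if self.start < 0 or self.duration < 0:
            raise DomainError("start and duration must be >= 0")


@dataclass(frozen=True)
class Regimen:
    """A repeated dosing schedule: events within a cycle, cycled n times."""

    events: tuple
    cycle_length: float
    n_cycles: int = 1

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        if not self.cycle_length > 0 or self.n_cycles < 1:
            raise DomainError("cycle_length must be > 0 and n_cycles >= 1")
        for ev in self.events:
            if ev.start + ev.duration > self.cycle_length:
                raise DomainError("dose events must fall within the cycle length")

    @property
    def horizon(self) -> float:
        return self.cycle_length * self.n_cycles

    def expanded(self, drug: str) -> list[DoseEvent]:
        """All absolute-time events for one drug across cycles."""
        out = []
        for cyc in range(self.n_cycles):
            t0 = cyc * self.cycle_length
            for ev in self.events:
                if ev.drug.lower() == drug.lower():
                    out.append(DoseEvent(ev.drug, ev.dose, t0 + ev.start, ev.duration))
        return sorted(out, key=lambda e: e.start)

    @classmethod
    def q3w(cls, dose_dox: float = 50.0, dose_dex: float | None = 500.0,
            n_cycles: int = 3, *, dox_duration: float = 0.5,
            dex_duration: float = 0.25, dex_lead: float = 0.5) -> "Regimen":
        """Standard 3-weekly regimen: DOX 50 mg/m2 (0.5 h infusion) every
        21 days, optionally preceded by DEX 500 mg/m2 (15-min infusion
        finishing ``dex_lead`` h before the DOX start, per clinical
        convention of giving the cardioprotectant first)."""
        events = []
        dox_start = dex_lead + dex_duration if dose_dex else 0.0
        if dose_dex:
            events.append(DoseEvent("dex", dose_dex, 0.0, dex_duration))
        events.append(DoseEvent("dox", dose_dox, dox_start, dox_duration))
        return cls(tuple(events), cycle_length=21 * 24.0, n_cycles=n_cycles)


def _propagate(a: np.ndarray, x0: np.ndarray, rate_in: float, dt: np.ndarray) -> np.ndarray:
    """Exact solution of x' = A x + b (b = rate into compartment 0) at lags dt."""
    n = a.shape[0]
    b = np.zeros(n)
    b[0] = rate_in
    w, v = np.linalg.eig(a)
    vinv = np.linalg.inv(v)
    xp = -np.linalg.solve(a, b) if rate_in != 0 else np.zeros(n)
    coef = vinv @ (x0 - xp)
    # shape (n, len(dt)); eigenvalues can be complex-conjugate, result is real
    x = xp[:, None] + (v @ (np.exp(np.outer(w, dt)) * coef[:, None]))
    return np.real(x)


def simulate_pk(
    pk: PKParams, regimen: Regimen, t_grid: Sequence[float], drug: str
) -> ConcentrationProfile:
    """Plasma concentration profile (uM) for one drug under a regimen.

    Solved segment-by-segment between dosing breakpoints with the exact
    linear-system solution; evaluation at arbitrary ``t_grid`` points.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be 1-D strictly increasing")
    if t_grid[0] < 0:
        raise DomainError("t_grid must be non-negative")
    events = regimen.expanded(drug)
    a = pk.rate_matrix()
    n = a.shape[0]

    # breakpoints from time 0: every infusion start/end up to the grid end,
    # so doses administered before the first requested time still count
    pts = {0.0, t_grid[-1]}
    for ev in events:
        if ev.start <= t_grid[-1]:
            pts.add(ev.start)
            if ev.duration > 0:
                pts.add(min(ev.start + ev.duration, t_grid[-1]))
    bps = np.array(sorted(pts))

    conc_mg_l = np.zeros_like(t_grid)
    x = np.zeros(n)
    for left, right in zip(bps[:-1], bps[1:]):
        # boluses fire at the segment's left edge
        for ev in events:
            if ev.duration == 0 and np.isclose(ev.start, left):
                x[0] += ev.dose
        rate = sum(ev.dose / ev.duration for ev in events
                   if ev.duration > 0 and ev.start <= left < ev.start + ev.duration - 1e-12)
        mask = (t_grid >= left) & (t_grid < right)
        if np.any(mask):
            vals = _propagate(a, x, rate, t_grid[mask] - left)
            conc_mg_l[mask] = vals[0] / pk.v1
        x = _propagate(a, x, rate, np.array([right - left]))[:, 0]
    # boluses exactly at the final time point
    for ev in events:
        if ev.duration == 0 and np.isclose(ev.start, bps[-1]):
            x[0] += ev.dose
    conc_mg_l[t_grid >= bps[-1]] = x[0] / pk.v1

    conc_um = np.clip(conc_mg_l, 0.0, None) / pk.mw * 1000.0
    return ConcentrationProfile(t_grid, conc_um, site="plasma")
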