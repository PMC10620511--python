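"""Simultaneous fitting of the dynamic PD model to time-course viability data.

The model of :mod:`combopd.pdmodel` is fitted jointly to control,
single-agent and combination arms by naive-pooled nonlinear least squares:
every record contributes one residual, arms share one parameter vector, and
all positive parameters are estimated on the log scale (which both enforces
positivity and makes the reported %RSE a relative standard error directly).

Staged workflow mirroring common practice for such models:

* ``stage='single_agents'`` — control + single-agent arms; frees kg and the
  per-drug kill parameters (Smax, SC50, tau); psi fixed at 1.
* ``stage='combination'`` — combination arms only; all single-agent
  parameters fixed (at the supplied init/fixed values) and psi alone free.
* ``stage='all'`` — every arm simultaneously, freeing kg, both drugs'
  parameters and psi.

r0 is fixed at 100% by default (a viability assay is normalized to its
vehicle control); pass it in ``fixed`` with another value, or add "r0" to
``free_r0`` via ``fixed=None`` semantics if it must be estimated.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ViabilityDataset
from .errors import DomainError, EstimationError
from .fitutil import FitReport, least_squares_fit
from .pdmodel import DegradationParams, DrugKillParams, PDParams, simulate_pd

__all__ = ["CellPDModel", "CellPDResults", "profile_objective"]

_ALL_NAMES = (
    "kg", "smax_dox", "sc50_dox", "tau_dox",
    "smax_dex", "sc50_dex", "tau_dex", "psi",
)


def _flatten(p: PDParams) -> dict[str, float]:
    return {
        "r0": p.r0, "kg": p.kg,
        "smax_dox": p.dox.smax, "sc50_dox": p.dox.sc50, "tau_dox": p.dox.tau,
        "smax_dex": p.dex.smax, "sc50_dex": p.dex.sc50, "tau_dex": p.dex.tau,
        "psi": p.psi,
    }


def _unflatten(d: Mapping[str, float], psi_on: str = "dox") -> PDParams:
    return PDParams(
        r0=d["r0"], kg=d["kg"],
        dox=DrugKillParams(d["smax_dox"], d["sc50_dox"], d["tau_dox"]),
        dex=DrugKillParams(d["smax_dex"], d["sc50_dex"], d["tau_dex"]),
        psi=d["psi"], psi_on=psi_on,
    )


class CellPDModel:
    """Dynamic cell-kill model bound to a multi-arm time-course dataset."""

    def __init__(self, data: ViabilityDataset, deg: DegradationParams,
                 *, cell_line: str | None = None, psi_on: str = "dox"):
        df = data.frame if isinstance(data, ViabilityDataset) else ViabilityDataset(data).frame
        if cell_line is not None:
            df = df[df["cell_line"] == cell_line]
            if df.empty:
                raise EstimationError(f"no records for cell line {cell_line!r}")
        self.deg = deg
        self.psi_on = psi_on
        # group records into arms; each arm is simulated once per objective call
        self.arms: list[dict] = []
        for (ca, cb), grp in df.groupby(["conc_dox_uM", "conc_dex_uM"], sort=True):
            times = np.unique(grp["time_h"].to_numpy(dtype=float))
            sim_times = times if times[0] == 0 else np.concatenate(([0.0], times))
            idx = np.searchsorted(sim_times, grp["time_h"].to_numpy(dtype=float))
            self.arms.append({
                "c0_dox": float(ca), "c0_dex": float(cb),
                "sim_times": sim_times, "obs_idx": idx,
                "obs": grp["viability_pct"].to_numpy(dtype=float),
            })
        self.n_obs = int(sum(a["obs"].size for a in self.arms))
        if self.n_obs == 0:
            raise EstimationError("empty dataset")

    # ------------------------------------------------------------------
    def _has_control(self) -> bool:
        return any(a["c0_dox"] == 0 and a["c0_dex"] == 0 for a in self.arms)

    def _default_init(self, r0: float) -> PDParams:
        """Crude but scale-aware starting values from the data itself."""
        kg = 0.02
        ctrl = [a for a in self.arms if a["c0_dox"] == 0 and a["c0_dex"] == 0]
        if ctrl:
            a = ctrl[0]
            t_last = a["sim_times"][-1]
            if t_last > 0:
                last = float(np.mean(a["obs"][a["obs_idx"] == a["obs_idx"].max()]))
                kg = max(np.log(max(last, 1e-3) / r0) / t_last, 1e-4)
        def med_conc(key):
            vals = [a[key] for a in self.arms if a[key] > 0]
            return float(np.exp(np.mean(np.log(vals)))) if vals else 1.0
        return PDParams(
            r0=r0, kg=kg,
            dox=DrugKillParams(smax=max(2 * kg, 0.01), sc50=med_conc("c0_dox"), tau=20.0),
            dex=DrugKillParams(smax=max(2 * kg, 0.01), sc50=med_conc("c0_dex"), tau=20.0),
            psi=1.0, psi_on=self.psi_on,
        )

    def _select_arms(self, stage: str) -> list[dict]:
        if stage == "single_agents":
            return [a for a in self.arms if a["c0_dox"] == 0 or a["c0_dex"] == 0]
        if stage == "combination":
            return [a for a in self.arms if a["c0_dox"] > 0 and a["c0_dex"] > 0]
        if stage == "all":
            return self.arms
        raise DomainError(f"unknown stage {stage!r}")

    def _free_names(self, stage: str, arms: list[dict], fixed: dict) -> list[str]:
        has_dox = any(a["c0_dox"] > 0 for a in arms)
        has_dex = any(a["c0_dex"] > 0 for a in arms)
        if stage == "combination":
            names = ["psi"]
        else:
            names = ["kg"]
            if has_dox:
                names += ["smax_dox", "sc50_dox", "tau_dox"]
            if has_dex:
                names += ["smax_dex", "sc50_dex", "tau_dex"]
            if stage == "all" and any(a["c0_dox"] > 0 and a["c0_dex"] > 0 for a in arms):
                names.append("psi")
        return [n for n in names if n not in fixed]

    def _objective_arms(self, arms, base: dict, free: list[str], rtol: float, atol: float):
        def predict(theta: np.ndarray) -> np.ndarray:
            vals = dict(base)
            vals.update(zip(free, theta))
            p = _unflatten(vals, self.psi_on)
            preds = []
            for a in arms:
                traj = simulate_pd(p, self.deg, a["c0_dox"], a["c0_dex"],
                                   a["sim_times"], rtol=rtol, atol=atol)
                preds.append(traj["viability_pct"].to_numpy()[a["obs_idx"]])
            return np.concatenate(preds)
        return predict

    # ------------------------------------------------------------------
    def fit(
        self,
        stage: str = "all",
        fixed: Mapping[str, float] | None = None,
        init: PDParams | None = None,
        *,
        n_starts: int = 5,
        seed: int = 0,
        loss: str = "ols",
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> "CellPDResults":
        fixed = dict(fixed or {})
        r0 = float(fixed.pop("r0", init.r0 if init is not None else 100.0))
        arms = self._select_arms(stage)
        if not arms:
            raise EstimationError(f"no arms available for stage {stage!r}")
        if init is None:
            init = self._default_init(r0)
        base = _flatten(replace(init, r0=r0))
        base.update(fixed)

        free = self._free_names(stage, arms, fixed)
        if not free:
            raise EstimationError("no free parameters for this stage/fixed combination")
        if "kg" in free and not any(a["c0_dox"] == 0 and a["c0_dex"] == 0 for a in arms):
            raise EstimationError("growth rate kg is free but no control arm is present")
        if ("tau_dox" in free or "tau_dex" in free) and all(
            a["sim_times"][-1] == 0 for a in arms
        ):
            raise EstimationError("transit times requested but no post-baseline observations")

        observed = np.concatenate([a["obs"] for a in arms])
        predict = self._objective_arms(arms, base, free, rtol, atol)
        x0 = np.array([base[n] for n in free], dtype=float)
        weights = None
        if loss == "proportional":
            weights = 1.0 / np.clip(predict(x0), 1e-6, None)
        elif loss != "ols":
            raise DomainError(f"unknown loss {loss!r}")

        out = least_squares_fit(
            predict, observed, x0,
            n_starts=n_starts, seed=seed, weights=weights,
            xtol=1e-10, ftol=1e-10,
        )
        estimates = dict(base)
        estimates.update(zip(free, out["x"]))
        fixed_names = tuple(["r0"] + [n for n in _ALL_NAMES if n not in free])
        report = FitReport(
            estimates={k: float(estimates[k]) for k in ("r0",) + _ALL_NAMES},
            rse_pct=dict(zip(free, (float(r) for r in out["rse_pct"]))),
            objective=out["objective"],
            converged=out["converged"],
            n_obs=observed.size,
            fixed=fixed_names,
            message=out["message"],
            n_starts=n_starts,
            extra={"stage": stage},
        )
        return CellPDResults(self, report)


class CellPDResults:
    """Results of a :class:`CellPDModel` fit."""

    def __init__(self, model: CellPDModel, report: FitReport):
        self.model = model
        self._report = report
        self.estimates = report.estimates
        self.params = _unflatten(report.estimates, model.psi_on)
        self.rse_pct = report.rse_pct
        self.objective = report.objective
        self.converged = report.converged
        self.n_obs = report.n_obs
        self.fixed = report.fixed
        self.stage = report.extra.get("stage")

    @property
    def interaction_class(self) -> str:
        psi = self.params.psi
        if abs(psi - 1.0) <= 0.05:
            return "additive"
        return "antagonistic" if psi > 1.0 else "synergistic"

    def predict(self, c0_dox: float, c0_dex: float, t_grid) -> pd.DataFrame:
        return simulate_pd(self.params, self.model.deg, c0_dox, c0_dex, t_grid)

    def summary(self) -> str:
        lines = self._report.summary_lines(
            f"Cellular PD model fit (stage: {self.stage})"
        )
        lines.append(
            "mean transit times: "
            f"tau_dox = {self.params.dox.tau:.3g} h, tau_dex = {self.params.dex.tau:.3g} h"
        )
        lines.append(f"interaction (psi = {self.params.psi:.3g}): {self.interaction_class}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "rse_pct": self.rse_pct,
            "objective": self.objective,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "fixed": list(self.fixed),
            "stage": self.stage,
        }


def profile_objective(
    model: CellPDModel,
    name: str,
    grid: Sequence[float],
    *,
    stage: str = "all",
    fixed: Mapping[str, float] | None = None,
    init: PDParams | None = None,
    n_starts: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Objective profile for one parameter: re-fit the rest at each grid value.

    Returns a frame (value, objective); the profile minimum sits at the joint
    estimate when the grid contains it. Useful as a cheap identifiability
    diagnostic for psi and the transit times.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DomainError("profile grid must be non-empty")
    if name not in _ALL_NAMES:
        raise DomainError(f"unknown parameter {name!r}")
    rows = []
    for value in grid:
        fx = dict(fixed or {})
        fx[name] = float(value)
        try:
            res = model.fit(stage=stage, fixed=fx, init=init,
                            n_starts=n_starts, seed=seed)
            rows.append((value, res.objective))
        except EstimationError:
            # e.g. profiling the only free parameter of the stage: evaluate
            base = _flatten(init if init is not None else model._default_init(100.0))
            base.update(fx)
            arms = model._select_arms(stage)
            pred = model._objective_arms(arms, base, [], 1e-8, 1e-10)(np.empty(0))
            obs = np.concatenate([a["obs"] for a in arms])
            rows.append((value, float(np.sum((pred - obs) ** 2))))
    return pd.DataFrame(rows, columns=["value", "objective"])
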