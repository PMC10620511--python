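"""Viability datasets and synthetic CCK-8-style data generation.

The canonical tabular schema (one row per well reading) is:

    cell_line, conc_dox_uM, conc_dex_uM, time_h, replicate, viability_pct

The generators emulate the checkerboard design used in combination
cytotoxicity studies of doxorubicin and dexrazoxane in breast cancer cells:
6 DOX concentrations (0.005-1 uM), 6 DEX concentrations (6.25-200 uM), their
36 pairwise combinations plus a vehicle control, read out either at a single
static endpoint (72 h) or as 0-96 h time courses, with >= 3 replicates and
multiplicative lognormal measurement noise (viability readouts are positive
with roughly constant CV). Additive Gaussian noise is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .interaction import CombinationParams, competitive_response
from .pdmodel import DegradationParams, PDParams, simulate_pd

__all__ = [
    "REQUIRED_COLUMNS",
    "DOX_GRID",
    "DEX_GRID",
    "ViabilityDataset",
    "DesignSpec",
    "generate_static",
    "generate_timecourse",
]

REQUIRED_COLUMNS = (
    "cell_line", "conc_dox_uM", "conc_dex_uM", "time_h", "replicate", "viability_pct",
)

# Study-design concentration grids (uM). The printed ranges are 0.005-1 uM
# (DOX) and 6.25-200 uM (DEX); intermediate levels follow the half-log /
# two-fold ladders conventional for such designs.
DOX_GRID = (0.005, 0.01, 0.05, 0.1, 0.5, 1.0)
DEX_GRID = (6.25, 12.5, 25.0, 50.0, 100.0, 200.0)


class ViabilityDataset:
    """Thin validated wrapper around the canonical viability DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(f"missing required column(s): {', '.join(missing)}")
        df = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in ("conc_dox_uM", "conc_dex_uM", "viability_pct"):
            if (df[col] < 0).any():
                raise DataError(f"negative values in column {col}")
        if (df["replicate"] < 1).any():
            raise DataError("replicate indices must be >= 1")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path, units: str = "uM") -> "ViabilityDataset":
        """Read the canonical CSV; ``units='nM'`` converts concentrations."""
        df = pd.read_csv(path)
        # accept the single-drug long form (drug / conc_uM) and widen it
        if "drug" in df.columns and "conc_uM" in df.columns:
            wide = df.copy()
            drug = wide.pop("drug").str.lower()
            conc = wide.pop("conc_uM")
            wide["conc_dox_uM"] = np.where(drug == "dox", conc, 0.0)
            wide["conc_dex_uM"] = np.where(drug == "dex", conc, 0.0)
            df = wide
        if units == "nM":
            for col in ("conc_dox_uM", "conc_dex_uM"):
                if col in df.columns:
                    df[col] = df[col] / 1000.0
        elif units != "uM":
            raise DomainError(f"units must be 'uM' or 'nM', got {units!r}")
        return cls(df)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # --- arm selectors -------------------------------------------------
    def control(self) -> pd.DataFrame:
        f = self.frame
        return f[(f.conc_dox_uM == 0) & (f.conc_dex_uM == 0)]

    def single_agent(self, drug: str) -> pd.DataFrame:
        f = self.frame
        if drug.lower() == "dox":
            return f[(f.conc_dox_uM > 0) & (f.conc_dex_uM == 0)]
        return f[(f.conc_dex_uM > 0) & (f.conc_dox_uM == 0)]

    def combinations(self) -> pd.DataFrame:
        f = self.frame
        return f[(f.conc_dox_uM > 0) & (f.conc_dex_uM > 0)]


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design for synthetic data generation.

    Defaults reproduce the study conditions: the 6x6 checkerboard with
    combinations, observation times {0, 24, 48, 72, 96} h for time courses
    (72 h alone for static endpoints), 3 replicates, 10% CV noise.
    """

    dox_concs: tuple = DOX_GRID
    dex_concs: tuple = DEX_GRID
    include_combinations: bool = True
    times: tuple = (0.0, 24.0, 48.0, 72.0, 96.0)
    n_replicates: int = 3
    noise_cv: float = 0.10
    seed: int = 0
    cell_line: str = "synthetic"
    noise_model: str = "lognormal"  # or "gaussian"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise DomainError("noise_model must be 'lognormal' or 'gaussian'")
        if any(c < 0 for c in self.dox_concs) or any(c < 0 for c in self.dex_concs):
            raise DomainError("design concentrations must be >= 0")

    def arms(self) -> list[tuple[float, float]]:
        """(conc_dox, conc_dex) arms: control, margins, and combinations."""
        out = [(0.0, 0.0)]
        out += [(c, 0.0) for c in self.dox_concs if c > 0]
        out += [(0.0, c) for c in self.dex_concs if c > 0]
        if self.include_combinations:
            out += [(a, b) for a in self.dox_concs if a > 0
                    for b in self.dex_concs if b > 0]
        return out


def _apply_noise(mean: np.ndarray, design: DesignSpec, rng: np.random.Generator) -> np.ndarray:
    if design.noise_cv == 0:
        return mean
    if design.noise_model == "lognormal":
        # exp(N(0, sigma)) multiplier with sigma chosen so the sample CV is noise_cv
        sigma = np.sqrt(np.log1p(design.noise_cv**2))
        return mean * rng.lognormal(0.0, sigma, size=mean.shape)
    return np.clip(mean + rng.normal(0.0, design.noise_cv * mean, size=mean.shape), 0.0, None)


def generate_static(
    design: DesignSpec, truth: CombinationParams, time_h: float = 72.0
) -> ViabilityDataset:
    """Static endpoint dataset from the competitive interaction model.

    Every arm of the design (control, margins, combinations) is evaluated
    with :func:`~combopd.interaction.competitive_response` — margins reduce
    to the single-agent Hill curves when psi = 1 — then replicated with
    measurement noise. Reproducible for a fixed design seed.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for ca, cb in design.arms():
        mean = competitive_response(truth, ca, cb)
        vals = _apply_noise(np.full(design.n_replicates, mean), design, rng)
        for rep, v in enumerate(vals, start=1):
            rows.append((design.cell_line, ca, cb, time_h, rep, v))
    return ViabilityDataset(pd.DataFrame(rows, columns=REQUIRED_COLUMNS))


def generate_timecourse(
    design: DesignSpec, truth: PDParams, deg: DegradationParams
) -> ViabilityDataset:
    """Time-course dataset from the dynamic PD model.

    Mean trajectories per arm come from :func:`~combopd.pdmodel.simulate_pd`
    (single-agent arms simply have the other drug's c0 = 0; psi acts only
    when DOX is present). Times must include 0.
    """
    times = np.asarray(design.times, dtype=float)
    if times.size == 0 or times[0] != 0:
        raise DomainError("time-course designs must include t = 0 first")
    rng = np.random.default_rng(design.seed)
    rows = []
    for ca, cb in design.arms():
        mean = simulate_pd(truth, deg, ca, cb, times)["viability_pct"].to_numpy()
        noisy = _apply_noise(
            np.tile(mean, (design.n_replicates, 1)), design, rng
        )
        for rep in range(design.n_replicates):
            for t, v in zip(times, noisy[rep]):
                rows.append((design.cell_line, ca, cb, t, rep + 1, v))
    return ViabilityDataset(pd.DataFrame(rows, columns=REQUIRED_COLUMNS))
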