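"""Time-indexed drug concentration profiles at a named site."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["ConcentrationProfile"]


@dataclass(frozen=True)
class ConcentrationProfile:
    """A drug concentration time series (uM) at a site.

    times are hours, strictly increasing; concentrations are non-negative.
    site is one of 'medium', 'plasma', 'tumor' (free-form labels allowed).
    Evaluation between grid points is linear; before the first time point
    the concentration is 0 (nothing has been dosed yet).
    """

    times: np.ndarray
    concentrations: np.ndarray
    site: str = "plasma"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.shape != c.shape or t.size == 0:
            raise DomainError("times and concentrations must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(c < 0):
            raise DomainError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __call__(self, t):
        """Linear interpolation; 0 before the profile start, held at the
        last value after the end (callers should cover their grid)."""
        return np.interp(t, self.times, self.concentrations, left=0.0)

    def scaled(self, factor: float, site: str | None = None) -> "ConcentrationProfile":
        if not factor > 0:
            raise DomainError(f"scale factor must be > 0, got {factor}")
        return replace(
            self,
            concentrations=self.concentrations * factor,
            site=site if site is not None else self.site,
        )

    def auc(self) -> float:
        """Linear-trapezoid area under the curve (uM*h) on the profile's grid."""
        return float(np.trapezoid(self.concentrations, self.times))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times,
            f"conc_{self.site}_uM": self.concentrations,
        })
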