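"""Published and default parameter sets for the DOX/DEX breast-cancer study.

Static (72 h) single-agent Hill estimates and dynamic cell-kill model
estimates for the JIMT-1 (HER2+, trastuzumab-resistant) and MDA-MB-468
(triple-negative) cell lines are the literature values this package's
worked examples and self-consistency checks are built around. Concentrations
are uM throughout; the dynamic tables report transit rate constants 1/tau,
stored here as mean transit times tau = 1/rate.

The clinical PK parameter sets are SYNTHETIC defaults: the source study drew
its compartmental PK from earlier literature without printing the values, so
the sets below were constructed once to give clinically plausible profiles
(doxorubicin: triphasic, high distribution volume, terminal half-life around
30 h; dexrazoxane: biphasic, half-life a few hours). Replace them with fitted
values for any quantitative PK work.
"""

from __future__ import annotations

from .hill import HillParams
from .interaction import CombinationParams
from .pdmodel import DegradationParams, DrugKillParams, PDParams
from .pk import MW_DEX, MW_DOX, PKParams

__all__ = [
    "STATIC_HILL",
    "STATIC_PSI",
    "static_combination",
    "PD_PARAMS",
    "DEGRADATION",
    "SYNTHETIC_PK_DOX",
    "SYNTHETIC_PK_DEX",
]

# --- static 72-h concentration-response estimates (gamma fixed at 1) -----
STATIC_HILL: dict[str, dict[str, HillParams]] = {
    "JIMT-1": {
        "dox": HillParams(r0=106.0, imax=0.988, ic50=0.214),   # IC50 214 nM
        "dex": HillParams(r0=106.0, imax=0.74, ic50=97.5),
    },
    "MDA-MB-468": {
        "dox": HillParams(r0=100.0, imax=0.959, ic50=0.0211),  # IC50 21.1 nM; r0 fixed
        "dex": HillParams(r0=110.0, imax=0.825, ic50=36.0),
    },
}

# static interaction estimates from the competitive interaction model
STATIC_PSI: dict[str, float] = {"JIMT-1": 1.11, "MDA-MB-468": 0.84}


def static_combination(cell_line: str, psi: float | None = None) -> CombinationParams:
    """Combination parameter set for a cell line (drug A = DOX, B = DEX)."""
    hills = STATIC_HILL[cell_line]
    return CombinationParams(
        hills["dox"], hills["dex"],
        psi=STATIC_PSI[cell_line] if psi is None else psi,
    )


# --- dynamic cellular PD model estimates ---------------------------------
# tau values are reciprocals of the reported transit rate constants:
# JIMT-1: 1/0.0703 and 1/0.0335 h; MDA-MB-468: 1/0.0275 and 1/0.0182 h.
PD_PARAMS: dict[str, PDParams] = {
    "JIMT-1": PDParams(
        r0=100.0, kg=0.0171,
        dox=DrugKillParams(smax=0.0705, sc50=0.315, tau=1.0 / 0.0703),
        dex=DrugKillParams(smax=0.0482, sc50=21.2, tau=1.0 / 0.0335),
        psi=2.0,
    ),
    "MDA-MB-468": PDParams(
        r0=100.0, kg=0.0167,
        dox=DrugKillParams(smax=1.16, sc50=0.761, tau=1.0 / 0.0275),
        dex=DrugKillParams(smax=0.29, sc50=17.5, tau=1.0 / 0.0182),
        psi=1.0,
    ),
}

# first-order loss of drug in culture medium (fixed inputs, never fitted)
DEGRADATION = DegradationParams(kdeg_dox=0.022, kdeg_dex=0.054)

# --- synthetic clinical PK defaults (see module docstring) ---------------
SYNTHETIC_PK_DOX = PKParams(
    model="3cpt", v1=14.0, cl=30.0, mw=MW_DOX,
    q2=30.0, v2=40.0, q3=25.0, v3=900.0,
)
SYNTHETIC_PK_DEX = PKParams(
    model="2cpt", v1=11.0, cl=7.9, mw=MW_DEX,
    q2=8.0, v2=12.0,
)
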