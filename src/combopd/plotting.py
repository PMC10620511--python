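"""Optional quick-look plots (response surfaces and viability trajectories)."""

from __future__ import annotations

import numpy as np

from .interaction import CombinationParams, additive_surface


def plot_surface(params: CombinationParams, grid_a, grid_b, data=None, ax=None):
    """3D additive response surface with observed points overlaid.

    Points above the surface (antagonistic direction) are drawn red, points
    at/below (additive/synergistic) blue. Returns the axes.
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    ga, gb = np.meshgrid(grid_a, grid_b, indexing="ij")
    surf = additive_surface(params, grid_a, grid_b)
    ax.plot_surface(np.log10(ga), np.log10(gb), surf, alpha=0.5, cmap="viridis")
    if data is not None:
        from .interaction import classify_against_surface

        df = data.frame if hasattr(data, "frame") else data
        cls = classify_against_surface(df, params)
        above = cls.residuals > 0
        with np.errstate(divide="ignore"):
            x = np.log10(df["conc_dox_uM"].to_numpy())
            y = np.log10(df["conc_dex_uM"].to_numpy())
        z = df["viability_pct"].to_numpy()
        ax.scatter(x[above], y[above], z[above], color="red", s=12)
        ax.scatter(x[~above], y[~above], z[~above], color="blue", s=12)
    ax.set_xlabel("log10 DOX (uM)")
    ax.set_ylabel("log10 DEX (uM)")
    ax.set_zlabel("viability (%)")
    return ax


def plot_trajectories(trajectories: dict, ax=None, logy: bool = True):
    """Overlay viability-time trajectories; keys are arm labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, traj in trajectories.items():
        ax.plot(traj["time_h"], traj["viability_pct"], label=label)
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("viability (%)")
    ax.legend(fontsize=8)
    return ax
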