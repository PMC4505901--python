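"""Optional figure rendering (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np


def plot_r_surface(grid_result, ax=None):
    """Contour plot of the R(B, K) surface with the best-ratio ray."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    B, K = grid_result.grid_b, grid_result.grid_k
    cs = ax.contourf(K, B, grid_result.r_surface, levels=20, cmap="jet")
    if np.isfinite(grid_result.best_ratio):
        k = np.linspace(0, K[-1], 50)
        ax.plot(k, grid_result.best_ratio * k, "w--", lw=1.5,
                label=f"B/K = {grid_result.best_ratio:.2f}")
        ax.set_ylim(0, B[-1])
        ax.legend(loc="upper right")
    ax.set_xlabel("K (Nm/rad)")
    ax.set_ylabel("B (Nm s/rad)")
    ax.figure.colorbar(cs, ax=ax, label="mean R (x, y)")
    return ax


def plot_tuning_polar(fits: dict, ax=None):
    """Polar summary of per-muscle preferred directions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    for name, fit in fits.items():
        theta = np.deg2rad(fit.pd)
        ax.annotate(
            "", xy=(theta, fit.modulation_depth), xytext=(0, 0),
            arrowprops={"arrowstyle": "->", "lw": 2},
        )
        ax.text(theta, fit.modulation_depth * 1.1, f"{name} {fit.pd:.0f}°",
                ha="center")
    ax.set_rlabel_position(225)
    return ax


def plot_agonist_bars(rows, ax=None):
    """Per-direction displacement vs velocity correlation bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(len(rows))
    ax.bar(x - 0.2, [r.r_displacement for r in rows], width=0.4,
           label="agonist vs displacement")
    ax.bar(x + 0.2, [r.r_velocity for r in rows], width=0.4,
           label="agonist vs velocity")
    ax.set_xticks(x, [r.direction for r in rows])
    ax.set_ylabel("Pearson R")
    ax.legend()
    return ax
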