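"""Occupancy-map rendering of a lattice world."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .world import INFECTED, UNINFECTED, GridState

__all__ = ["plot_grid"]


def plot_grid(grid: GridState, path=None, ax=None):
    """Render EPS shading with cell and phage markers.

    EPS patches are shaded; uninfected cells are green dots, infected
    cells orange, and free phage blue dots scaled by local count.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    h, w = grid.shape
    ax.imshow(grid.eps, cmap="Greys", alpha=0.3, origin="lower",
              extent=(-0.5, w - 0.5, -0.5, h - 0.5))
    for code, color, label in ((UNINFECTED, "tab:green", "uninfected"),
                               (INFECTED, "tab:orange", "infected")):
        rr, cc = np.nonzero(grid.occupant == code)
        if rr.size:
            ax.scatter(cc, rr, s=12, c=color, label=label, marker="o")
    rr, cc = np.nonzero(grid.phage > 0)
    if rr.size:
        sizes = 2 + 3 * np.log1p(grid.phage[rr, cc])
        ax.scatter(cc, rr, s=sizes, c="tab:blue", label="phage", marker="x",
                   linewidths=0.8)
    ax.set_xlim(-0.5, w - 0.5)
    ax.set_ylim(-0.5, h - 0.5)
    ax.set_title(f"step {grid.step}")
    ax.legend(loc="upper right", fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
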