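"""Minimal topographic map rendering (interpolated disc plots)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .montage import Montage

__all__ = ["plot_topomap"]


def plot_topomap(montage: Montage, scalp_map: np.ndarray, path, title: str = "") -> None:
    """Render one scalp map (uV) as a filled-contour disc plot."""
    scalp_map = np.asarray(scalp_map, float)
    if scalp_map.shape != (montage.n_channels,):
        raise ValueError("map length must equal the montage channel count")
    fig, ax = plt.subplots(figsize=(4, 4))
    x, y = montage.positions.T
    lim = float(np.abs(scalp_map).max()) or 1.0
    tri = ax.tricontourf(x, y, scalp_map, levels=24, cmap="RdBu_r",
                         vmin=-lim, vmax=lim)
    ax.scatter(x, y, s=6, c="k", zorder=3)
    circle = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1)
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(title, fontsize=9)
    fig.colorbar(tri, ax=ax, shrink=0.75, label="uV")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
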