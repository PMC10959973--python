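"""Optional rendering of analysis outputs (matplotlib)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .pairs import CONTOUR_LEVELS, ComovingMap  # noqa: E402
from .triplets import TripletMap  # noqa: E402

__all__ = ["plot_comoving_map", "plot_triplet_map", "plot_op_or_density"]


def plot_comoving_map(cmap: ComovingMap, path=None, ax=None):
    """Render a comoving pair-correlation map with the standard
    0.1 ... 0.9 contour levels."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    z = cmap.intensity.T  # imshow wants (row=y, col=x)
    extent = [cmap.x_edges[0], cmap.x_edges[-1],
              cmap.y_edges[0], cmap.y_edges[-1]]
    ax.imshow(z, origin="lower", extent=extent, cmap="Purples")
    ax.contour(cmap.x_centers, cmap.y_centers, z, levels=CONTOUR_LEVELS,
               colors="k", linewidths=0.5)
    ax.set_xlabel("x' (L)")
    ax.set_ylabel("y' (L)")
    ax.set_title(f"g2 ({cmap.pair_mode}{', ' + cmap.state_filter if cmap.state_filter else ''})")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_triplet_map(tmap: TripletMap, path=None):
    """Observed map, Kirkwood prediction and their difference."""
    n_panels = 3 if tmap.g3k is not None else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 4))
    axes = np.atleast_1d(axes)
    extent = [tmap.x_edges[0], tmap.x_edges[-1],
              tmap.y_edges[0], tmap.y_edges[-1]]
    panels = [(tmap.g3, "observed g3")]
    if tmap.g3k is not None:
        panels += [(tmap.g3k, "Kirkwood g3K"),
                   (tmap.g3 - tmap.g3k, "g3 - g3K")]
    for ax, (z, title) in zip(axes, panels):
        im = ax.imshow(z.T, origin="lower", extent=extent, cmap="RdBu_r"
                       if "-" in title else "Purples")
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(title)
        ax.set_xlabel("x3~ (L)")
    axes[0].set_ylabel("y3~ (L)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_op_or_density(counts, op_edges, or_edges, path=None):
    """Frame-count density on the (O_p, O_r) plane."""
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(counts.T, origin="lower", extent=[0, 1, 0, 1],
                   cmap="Greys")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("O_p")
    ax.set_ylabel("O_r")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
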