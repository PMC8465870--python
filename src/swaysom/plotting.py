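"""Map diagnostics plots: U-matrix, hit counts and weight planes.

Hexagonal grids are drawn as offset scatter maps in layout space;
rectangular grids as plain images.  Colors encode structure only (darker =
larger neighbour distance on the U-matrix), not any particular palette.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .som import SOMModel, hits as som_hits, u_matrix, weight_planes


def _grid_scatter(ax, model: SOMModel, values: np.ndarray, title: str, cmap: str):
    pos = model.grid.positions
    sc = ax.scatter(
        pos[:, 0], pos[:, 1], c=values, cmap=cmap, s=220,
        marker="h" if model.grid.topology == "hexagonal" else "s",
        edgecolors="k", linewidths=0.3,
    )
    ax.set_title(title)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xticks([])
    ax.set_yticks([])
    return sc


def plot_u_matrix(model: SOMModel, path: str | Path) -> Path:
    """Neighbourhood-distance map; bright regions separate clusters."""
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = _grid_scatter(ax, model, u_matrix(model), "neighbourhood distance", "cividis")
    fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_hits(model: SOMModel, data: np.ndarray, path: str | Path) -> Path:
    """Per-neuron input-vector hit counts."""
    fig, ax = plt.subplots(figsize=(5, 5))
    counts = som_hits(data, model)
    sc = _grid_scatter(ax, model, counts, "input vector hits", "viridis")
    pos = model.grid.positions
    for (x, y), c in zip(pos, counts):
        if c:
            ax.text(x, y, str(c), ha="center", va="center", fontsize=6)
    fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_weight_planes(
    model: SOMModel, path: str | Path, feature_names: list[str] | None = None
) -> Path:
    """One panel per input feature showing that feature's weights across the
    map; visually similar planes indicate correlated features."""
    planes = weight_planes(model)
    d = planes.shape[0]
    names = feature_names or [f"feature {m}" for m in range(d)]
    fig, axes = plt.subplots(1, d, figsize=(4 * d, 4), squeeze=False)
    for m in range(d):
        sc = _grid_scatter(
            axes[0, m], model, planes[m].ravel(), names[m], "inferno"
        )
        fig.colorbar(sc, ax=axes[0, m], shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
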