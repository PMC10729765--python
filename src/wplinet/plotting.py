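"""Basic visualizations: connectivity heatmaps and differential-edge diagrams."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_connectivity_matrix(weights, channel_names, title: str = "", ax=None):
    """Heatmap of a symmetric wPLI matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(np.asarray(weights), vmin=0, vmax=max(1e-9, np.max(weights)),
                   cmap="viridis")
    ax.set_xticks(range(len(channel_names)), channel_names, rotation=90, fontsize=6)
    ax.set_yticks(range(len(channel_names)), channel_names, fontsize=6)
    ax.set_title(title)
    plt.colorbar(im, ax=ax, label="wPLI")
    return ax


def plot_edge_list(edges: list[dict] | str | Path, channel_names, ax=None):
    """Differential edges on a circular channel layout.

    ``edges`` is the JSON edge list a pipeline run writes
    (``top_edges_<band>.json``): red = increase in group A, blue = decrease.
    """
    if isinstance(edges, (str, Path)):
        edges = json.loads(Path(edges).read_text())
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    n = len(channel_names)
    theta = 2 * np.pi * np.arange(n) / n
    xy = np.c_[np.cos(theta), np.sin(theta)]
    idx = {nm: i for i, nm in enumerate(channel_names)}
    for e in edges:
        i, j = idx[e["node_i"]], idx[e["node_j"]]
        color = "crimson" if e["direction"] == "increase" else "royalblue"
        ax.plot(*zip(xy[i], xy[j]), color=color, lw=1.5, alpha=0.8)
    ax.scatter(xy[:, 0], xy[:, 1], s=60, c="k", zorder=3)
    for nm, (x, y) in zip(channel_names, xy):
        ax.annotate(nm, (1.12 * x, 1.12 * y), ha="center", va="center", fontsize=7)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
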