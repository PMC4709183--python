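"""Topographic display and tabular export of connectivity graphs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import ConnectivityGraph

__all__ = ["plot_connectivity_topomap", "export_matrix_csv", "ELECTRODE_XY_1020"]

#: Approximate 2-D head-plane coordinates (nose up, unit head radius) for the
#: 19 electrodes of the 10/20 montage.
ELECTRODE_XY_1020 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.52), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.40, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


def plot_connectivity_topomap(graph: ConnectivityGraph, ax=None,
                              significant_only: bool = True,
                              coords: dict | None = None):
    """Draw electrodes on a schematic scalp and connect (significant) pairs.

    Line width scales with the pair's window-averaged PLV. Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    coords = coords or ELECTRODE_XY_1020
    labels = graph.channel_labels or tuple(f"CH{i}" for i in range(graph.n_channels))
    xy = []
    for i, lab in enumerate(labels):
        if lab in coords:
            xy.append(coords[lab])
        else:  # fall back to a circle layout for non-10/20 labels
            ang = 2 * np.pi * i / graph.n_channels
            xy.append((0.9 * np.cos(ang), 0.9 * np.sin(ang)))
    xy = np.asarray(xy)

    head = plt.Circle((0, 0), 1.12, fill=False, lw=1.5)
    ax.add_patch(head)
    for i, j in graph.pairs:
        if significant_only:
            if graph.adjacency is None or not graph.adjacency[i, j]:
                continue
        w = graph.weights[i, j]
        ax.plot(
            [xy[i, 0], xy[j, 0]], [xy[i, 1], xy[j, 1]],
            color="tab:red", lw=0.5 + 3.0 * w, alpha=0.8,
        )
    ax.scatter(xy[:, 0], xy[:, 1], s=40, zorder=3, color="k")
    for (x, y), lab in zip(xy, labels):
        ax.annotate(lab, (x, y), textcoords="offset points", xytext=(3, 3),
                    fontsize=7)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def export_matrix_csv(graph: ConnectivityGraph, path) -> None:
    """Square weight matrix as CSV with channel-label headers."""
    labels = graph.channel_labels or tuple(f"CH{i}" for i in range(graph.n_channels))
    pd.DataFrame(graph.weights, index=labels, columns=labels).to_csv(path)
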