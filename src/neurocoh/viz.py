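"""Schematic head plots of group and difference graphs (matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .connectivity import DifferenceGraph, GroupGraph
from .montage import Montage


def _head_axes(ax, montage: Montage):
    pos = montage.position_array()
    r = 1.15 * max(1.0, float(abs(pos).max()))
    ax.add_patch(plt.Circle((0, 0), r, fill=False, lw=1.5))
    ax.plot([-0.12 * r, 0, 0.12 * r], [r, 1.12 * r, r], color="k", lw=1.5)  # nose
    ax.scatter(pos[:, 0], pos[:, 1], s=12, c="k", zorder=3)
    for (x, y), lab in zip(pos, montage.labels):
        ax.annotate(lab, (x, y), fontsize=5, ha="center", va="bottom",
                    xytext=(0, 3), textcoords="offset points")
    ax.set_xlim(-1.3 * r, 1.3 * r)
    ax.set_ylim(-1.3 * r, 1.3 * r)
    ax.set_aspect("equal")
    ax.axis("off")


def plot_group_graph(gg: GroupGraph, montage: Montage, path: str | Path) -> None:
    """Render a thresholded median-coherence graph to SVG/PNG."""
    fig, ax = plt.subplots(figsize=(4, 4))
    _head_axes(ax, montage)
    idx = {lab: i for i, lab in enumerate(montage.labels)}
    pos = montage.position_array()
    for a, b in sorted(gg.edges):
        ax.plot(*zip(pos[idx[a]], pos[idx[b]]), color="k", lw=0.7, alpha=0.7)
    ax.set_title(f"{gg.group} {gg.band}/{gg.condition} @ {gg.threshold:g}", fontsize=9)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def plot_difference_graph(dg: DifferenceGraph, montage: Montage, path: str | Path) -> None:
    """Render the significant case-deficit edges (blue) to SVG/PNG."""
    fig, ax = plt.subplots(figsize=(4, 4))
    _head_axes(ax, montage)
    idx = {lab: i for i, lab in enumerate(montage.labels)}
    pos = montage.position_array()
    for a, b in sorted(dg.edges):
        ax.plot(*zip(pos[idx[a]], pos[idx[b]]), color="tab:blue", lw=1.0)
    ax.set_title(f"case deficit {dg.band}/{dg.condition} (q≤{dg.q_cutoff:g})", fontsize=9)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
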