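"""Severity-map rendering: networks tinted by abnormality count."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .atlas import NETWORKS, SIDES

_TILE_COLORS = {"none": "#d9d9d9", "yellow": "#ffd92f",
                "orange": "#fc8d31", "red": "#d7191c"}


def plot_severity_map(severity: dict[tuple[str, str], dict], ax=None,
                      title: str | None = None):
    """One tile per (network, hemisphere), colored none/yellow/orange/red by
    the number of abnormal PVS measures (0/1/2/3)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.2))
    for i, net in enumerate(NETWORKS):
        for j, side in enumerate(SIDES):
            info = severity[(net, side)]
            ax.add_patch(Rectangle((j, len(NETWORKS) - 1 - i), 0.94, 0.94,
                                   facecolor=_TILE_COLORS[info["color"]],
                                   edgecolor="black"))
            ax.text(j + 0.47, len(NETWORKS) - 1 - i + 0.47,
                    str(info["n_significant"]), ha="center", va="center")
    ax.set_xticks([0.47, 1.47], [s.capitalize() for s in SIDES])
    ax.set_yticks([len(NETWORKS) - 1 - i + 0.47 for i in range(len(NETWORKS))],
                  [n.replace("_", "/") for n in NETWORKS])
    ax.set_xlim(-0.1, 2.05)
    ax.set_ylim(-0.1, len(NETWORKS) + 0.05)
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    for spine in ax.spines.values():
        spine.set_visible(False)
    ax.tick_params(length=0)
    return ax


def save_severity_figure(severity: dict[tuple[str, str], dict],
                         path: str | Path, title: str | None = None) -> None:
    ax = plot_severity_map(severity, title=title)
    ax.figure.savefig(str(path), dpi=120, bbox_inches="tight")
    plt.close(ax.figure)
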