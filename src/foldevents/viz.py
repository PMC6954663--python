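"""Annotated rendering of reactivity matrices.

The display clips reactivities at a ceiling (default 4) and rescales to
[0, 1] for the grayscale image only -- detection never sees the clipped
values.  Swings are drawn as boxes, ramps as lines, and events sharing a
concurrency group are connected in green.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Rectangle

from foldevents.events import EventTable
from foldevents.io import ReactivityMatrix

logger = logging.getLogger(__name__)

_DIR_COLOR = {"up": "tab:red", "down": "tab:blue"}


def plot_matrix(
    m: ReactivityMatrix,
    events: EventTable | None = None,
    ceiling: float = 4.0,
    out_path: str | None = None,
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Draw the matrix with optional event annotations; returns the axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    display = np.clip(m.values, 0.0, ceiling) / ceiling
    ax.imshow(
        display,
        cmap="gray",
        origin="lower",
        aspect="auto",
        interpolation="nearest",
        extent=(
            m.positions[0] - 0.5,
            m.positions[-1] + 0.5,
            m.lengths[0] - 0.5,
            m.lengths[-1] + 0.5,
        ),
        vmin=0.0,
        vmax=1.0,
    )
    ax.set_xlabel("nucleotide position")
    ax.set_ylabel("transcript length (nt)")

    groups: dict[str, list[tuple[float, float]]] = {}
    for e in events or ():
        if e.nucleotide not in m.positions or e.start_length not in m.lengths:
            logger.warning("event at nucleotide %d, length %d outside matrix; skipped",
                           e.nucleotide, e.start_length)
            continue
        color = _DIR_COLOR[e.direction]
        if e.class_ == "swing":
            ax.add_patch(
                Rectangle(
                    (e.nucleotide - 0.5, e.start_length - 0.5),
                    1.0,
                    e.end_length - e.start_length + 1.0,
                    fill=False,
                    edgecolor=color,
                    linewidth=1.2,
                )
            )
        else:
            ax.plot(
                [e.nucleotide, e.nucleotide],
                [e.start_length, e.end_length],
                color=color,
                linewidth=2.0,
            )
        if e.group_id:
            groups.setdefault(e.group_id, []).append((e.nucleotide, e.start_length))
    for pts in groups.values():
        pts = sorted(pts)
        ax.plot([p[0] for p in pts], [p[1] for p in pts],
                color="tab:green", linewidth=1.0, alpha=0.8)
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150)
        plt.close(ax.figure)
    return ax
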