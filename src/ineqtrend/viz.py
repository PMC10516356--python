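"""Prevalence-vs-prevalence trend figure.

One panel per stratum: the per-wave points (P(1), P(0)) labelled by
survey year, their mapped 95% confidence-region curves, the fitted trend
line extended to its first axis crossing, and green eradication markers
at (threshold, 0) and (0, threshold).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "ineqtrend"  # deterministic SVG ids
import matplotlib.pyplot as plt
import numpy as np

from .simulate import ConfidenceRegion, PrevalencePair
from .trend import TrendLine, axis_intersection

__all__ = ["plot_trend"]


def plot_trend(
    pairs: Sequence[PrevalencePair],
    regions: Sequence[ConfidenceRegion],
    line: TrendLine,
    threshold: float = 0.05,
    years: Sequence[int] | None = None,
    path: str | Path = "trend",
    title: str | None = None,
    formats: tuple[str, ...] = ("svg", "png"),
) -> list[Path]:
    """Draw the trend figure; returns the files written (one per format)."""
    if len(pairs) < 2:
        raise ValueError("need at least two waves to plot a trend")
    fig, ax = plt.subplots(figsize=(6, 6))

    for cr in regions:
        ax.plot(cr.boundary[:, 0], cr.boundary[:, 1], color="0.5", lw=0.8,
                gid="confidence-region")
    xs = [p.p1 for p in pairs]
    ys = [p.p0 for p in pairs]
    ax.scatter(xs, ys, color="C0", zorder=3, gid="wave-point")
    if years is not None:
        for x, y, yr in zip(xs, ys, years):
            ax.annotate(str(yr), (x, y), textcoords="offset points",
                        xytext=(5, 5), fontsize=8, gid="wave-label")

    x_cross, y_cross, axis = axis_intersection(line)
    x_end = x_cross if axis == "x-axis" else 0.0
    x_max = max(max(xs), max(np.max(cr.boundary[:, 0]) for cr in regions))
    grid = np.array([x_end, 1.05 * x_max])
    ax.plot(grid, line.intercept + line.slope * grid, color="C3", lw=1.5,
            gid="trend-line")
    if axis != "none":
        ax.scatter([x_cross], [y_cross], marker="x", color="C3", zorder=4,
                   gid="axis-crossing")

    ax.scatter([threshold, 0.0], [0.0, threshold], color="green", marker="o",
               zorder=4, gid="eradication-marker")

    lim = 1.1 * max(x_max, max(ys), threshold)
    ax.set_xlim(0.0, lim)
    ax.set_ylim(0.0, lim)
    ax.set_aspect("equal")
    ax.set_xlabel("P(1): prevalence at highest SES")
    ax.set_ylabel("P(0): prevalence at lowest SES")
    if title:
        ax.set_title(title)

    path = Path(path)
    written = []
    for fmt in formats:
        out = path.with_suffix(f".{fmt}")
        # strip date metadata so identical runs give identical files
        meta = {"Date": None} if fmt == "svg" else None
        fig.savefig(out, format=fmt, metadata=meta, dpi=150)
        written.append(out)
    plt.close(fig)
    return written
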