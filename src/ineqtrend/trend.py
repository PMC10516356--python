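"""Trend line through the per-wave prevalence pairs and eradication likelihood.

The trend is an unweighted ordinary least squares line of low-SES
prevalence ``P(0)`` on high-SES prevalence ``P(1)``, one point per survey
wave.  Travelling along the line in the direction of declining
prevalence, the first axis crossing summarises where the trend ends up:
the intercept if the y-axis is met first, or the x-axis crossing if the
line reaches zero low-SES prevalence before zero high-SES prevalence.
The *likelihood of eradication* is the fraction of simulated trend lines
whose first crossing lies within the eradication zone — less than 5%
prevalence (by default) on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrendLine",
    "TrendResult",
    "fit_trend",
    "axis_intersection",
    "eradication_likelihood",
    "summarize",
]


@dataclass
class TrendLine:
    """OLS line p0 = intercept + slope * p1 across waves."""

    slope: float
    intercept: float
    n_points: int


@dataclass
class TrendResult:
    """Trend line with simulation-based uncertainty for one stratum."""

    line: TrendLine
    intercept_ci: tuple[float, float]
    eradication_likelihood: float
    threshold: float
    n_sim: int
    per_sim_intercepts: np.ndarray
    per_sim_slopes: np.ndarray
    n_excluded: int = 0
    n_no_crossing: int = 0
    stratum: dict = field(default_factory=dict)


def fit_trend(points: Sequence[tuple[float, float]]) -> TrendLine:
    """Unweighted OLS of p0 on p1, one ``(p1, p0)`` point per wave.

    With exactly two waves the line interpolates both points.  All-equal
    ``p1`` values leave the slope undefined (vertical line) and raise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (p1, p0) points")
    p1, p0 = pts[:, 0], pts[:, 1]
    if np.ptp(p1) == 0:
        raise ValueError(f"all p1 values identical ({p1[0]}); trend line is vertical")
    slope, intercept = np.polyfit(p1, p0, 1)
    return TrendLine(slope=float(slope), intercept=float(intercept), n_points=len(pts))


def axis_intersection(line: TrendLine) -> tuple[float, float, str]:
    """First axis crossing travelling toward declining prevalence.

    Returns ``(x, y, axis)`` with ``axis`` one of ``"y-axis"``,
    ``"x-axis"`` or ``"none"``.  A nonnegative intercept means the y-axis
    is met first at ``(0, intercept)``.  A negative intercept with a
    positive slope means low-SES prevalence hits zero while high-SES
    prevalence is still positive: the x-axis crossing ``(-intercept/slope, 0)``.
    A negative intercept with non-positive slope leaves the feasible
    quadrant without crossing either axis at a nonnegative coordinate.
    """
    if line.intercept >= 0:
        return 0.0, line.intercept, "y-axis"
    if line.slope > 0:
        return -line.intercept / line.slope, 0.0, "x-axis"
    return float("nan"), float("nan"), "none"


def _ols_vectorized(p1: np.ndarray, p0: np.ndarray):
    """Row-wise OLS over (n_sim, n_waves) arrays; returns slopes, intercepts."""
    x_c = p1 - p1.mean(axis=1, keepdims=True)
    y_c = p0 - p0.mean(axis=1, keepdims=True)
    sxx = np.sum(x_c * x_c, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.sum(x_c * y_c, axis=1) / sxx
    intercepts = p0.mean(axis=1) - slopes * p1.mean(axis=1)
    return slopes, intercepts, sxx == 0


def eradication_likelihood(
    sim_points: np.ndarray,
    threshold: float = 0.05,
    points: Sequence[tuple[float, float]] | None = None,
    stratum: dict | None = None,
    max_excluded_frac: float = 0.01,
) -> TrendResult:
    """Fit one trend line per simulation draw and score eradication.

    Parameters
    ----------
    sim_points
        Array of shape ``(n_sim, n_waves, 2)``; draw *i* of wave *t*
        pairs with draw *i* of every other wave, last axis is
        ``(p1, p0)``.
    threshold
        Eradication cutoff: a line counts as eradicating when its first
        axis crossing exists and its nonzero coordinate lies in
        ``[0, threshold)``.
    points
        Optional per-wave point-estimate pairs ``(p1, p0)``; when given,
        the result's trend line is fitted to these instead of to the
        per-wave means of the draws.

    Returns a :class:`TrendResult` whose point-estimate line is the OLS
    fit to the point estimates, whose intercept CI is the
    2.5–97.5 percentile range of the simulated intercepts, and whose
    likelihood is the eradicating fraction of all ``n_sim`` draws
    (degenerate draws count as non-eradicating; more than
    ``max_excluded_frac`` of them aborts).
    """
    sim = np.asarray(sim_points, dtype=float)
    if sim.ndim != 3 or sim.shape[2] != 2:
        raise ValueError("sim_points must have shape (n_sim, n_waves, 2)")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    n_sim = sim.shape[0]
    p1, p0 = sim[:, :, 0], sim[:, :, 1]

    slopes, intercepts, degenerate = _ols_vectorized(p1, p0)
    n_excluded = int(degenerate.sum())
    if n_excluded > max_excluded_frac * n_sim:
        raise RuntimeError(
            f"{n_excluded}/{n_sim} simulations have identical p1 across waves; "
            "trend lines are not identifiable"
        )
    valid = ~degenerate

    # classify first axis crossing per simulated line
    y_first = valid & (intercepts >= 0)
    x_first = valid & (intercepts < 0) & (slopes > 0)
    no_cross = valid & (intercepts < 0) & (slopes <= 0)
    erad = np.zeros(n_sim, dtype=bool)
    erad[y_first] = intercepts[y_first] < threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        x_cross = -intercepts / slopes
    erad[x_first] = x_cross[x_first] < threshold

    if points is not None:
        line = fit_trend(points)
    else:
        line = fit_trend(np.column_stack([p1.mean(axis=0), p0.mean(axis=0)]))
    ic = intercepts[valid]
    ci = (float(np.percentile(ic, 2.5)), float(np.percentile(ic, 97.5)))
    return TrendResult(
        line=line,
        intercept_ci=ci,
        eradication_likelihood=float(erad.sum() / n_sim),
        threshold=threshold,
        n_sim=n_sim,
        per_sim_intercepts=intercepts,
        per_sim_slopes=slopes,
        n_excluded=n_excluded,
        n_no_crossing=int(no_cross.sum()),
        stratum=dict(stratum or {}),
    )


def _fmt_likelihood(frac: float) -> str:
    pct = 100.0 * frac
    if pct == 0:
        return "0"
    if pct < 1:
        return "<1"
    return f"{pct:.0f}"


def summarize(results: Sequence[TrendResult], region_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Results table: one row per (region, gender) stratum.

    Intercept and its CI are expressed as percentages; eradication
    likelihood renders as ``"<1"`` below 1%.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "region": r.stratum.get("region", "all"),
                "gender": r.stratum.get("gender", "all"),
                "intercept_pct": round(100.0 * r.line.intercept, 1),
                "ci_low_pct": round(100.0 * r.intercept_ci[0], 1),
                "ci_high_pct": round(100.0 * r.intercept_ci[1], 1),
                "slope": round(r.line.slope, 2),
                "eradication_pct": _fmt_likelihood(r.eradication_likelihood),
                "eradication_frac": r.eradication_likelihood,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "region", "gender", "intercept_pct", "ci_low_pct", "ci_high_pct",
            "slope", "eradication_pct", "eradication_frac",
        ],
    )
    if region_order and not df.empty:
        order = {r: i for i, r in enumerate(region_order)}
        df = df.sort_values(
            by=["region", "gender"],
            key=lambda s: s.map(order).fillna(len(order)) if s.name == "region" else s,
            kind="stable",
        ).reset_index(drop=True)
    return df
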