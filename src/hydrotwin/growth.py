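"""Fresh-weight prediction, growth rates, and the 12-stage size model.

Fresh weight is a linear model over five image-derived features

    Y = b0 + b1*height + b2*depth + b3*width + b4*area_side + b5*area_top

with coefficients fitted on the reference lettuce crop (heights/widths/depths
in cm, areas in cm^2). The fitted units of Y are those of the reference
model and are reported as model units.

Growth rate is the mean daily relative change of silhouette area; the
overall rate of a plant is the arithmetic mean of its side-view and top-view
rates. Growth stage is a 1-12 category obtained by dividing a reference
final area into twelve equal intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class FreshWeightModel:
    """Coefficients of the linear fresh-weight model (model units)."""

    intercept: float = 0.246012
    b_height: float = -0.000859
    b_depth: float = 0.001044
    b_width: float = 0.005135
    b_side_area: float = -0.000007
    b_top_area: float = 0.000042

    def __post_init__(self) -> None:
        for f in (self.intercept, self.b_height, self.b_depth, self.b_width,
                  self.b_side_area, self.b_top_area):
            if not np.isfinite(f):
                raise ValueError("all coefficients must be finite")


@dataclass(frozen=True)
class FeatureVector:
    """Morphometric inputs to the fresh-weight model; all must be >= 0."""

    height: float = 0.0      # cm
    depth: float = 0.0       # cm
    width: float = 0.0       # cm
    side_area: float = 0.0   # cm^2
    top_area: float = 0.0    # cm^2

    def __post_init__(self) -> None:
        for name in ("height", "depth", "width", "side_area", "top_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def predict_fresh_weight(features: FeatureVector,
                         model: FreshWeightModel = FreshWeightModel()) -> float:
    """Predicted fresh weight (model units) for one plant's features."""
    return (model.intercept
            + model.b_height * features.height
            + model.b_depth * features.depth
            + model.b_width * features.width
            + model.b_side_area * features.side_area
            + model.b_top_area * features.top_area)


@dataclass
class GrowthSeries:
    """Ordered (timestamp, area) observations for one plant and view."""

    instance_id: int
    view: str  # side | top | combined
    points: list[tuple[datetime, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be strictly increasing")
        if any(a < 0 for _, a in self.points):
            raise ValueError("areas must be >= 0")

    def daily_means(self) -> list[tuple[date, float]]:
        """Per-calendar-day mean area, in date order."""
        acc: dict[date, list[float]] = {}
        for t, a in self.points:
            acc.setdefault(t.date(), []).append(a)
        return [(d, float(np.mean(acc[d]))) for d in sorted(acc)]


@dataclass
class GrowthRateResult:
    """Mean daily relative growth with the per-day breakdown."""

    mean_rate: float                       # %
    per_day: list[tuple[date, float]]      # (day, % change from previous day)
    skipped: list[date] = field(default_factory=list)  # zero-area predecessors


def daily_growth_rate(series: GrowthSeries) -> GrowthRateResult:
    """Mean daily relative area growth (%) from daily-aggregated areas.

    Areas are first averaged per calendar day; the rate for day d is
    100*(A_d - A_{d-1})/A_{d-1} and the result is the arithmetic mean over
    days. Days whose predecessor mean is zero are skipped and flagged.
    """
    daily = series.daily_means()
    if len(daily) < 2:
        raise ValueError("need at least two days of observations")
    per_day: list[tuple[date, float]] = []
    skipped: list[date] = []
    for (d0, a0), (d1, a1) in zip(daily, daily[1:]):
        if a0 == 0:
            skipped.append(d1)
            continue
        per_day.append((d1, 100.0 * (a1 - a0) / a0))
    if not per_day:
        raise ValueError("no day pair with a nonzero starting area")
    return GrowthRateResult(float(np.mean([r for _, r in per_day])),
                            per_day, skipped)


def overall_growth_rate(side_rate: float, top_rate: float) -> float:
    """Overall daily growth (%): arithmetic mean of the two view rates."""
    if not (np.isfinite(side_rate) and np.isfinite(top_rate)):
        raise ValueError("rates must be finite")
    return (side_rate + top_rate) / 2.0


@dataclass(frozen=True)
class StageBoundaries:
    """Cut points c0=0 < c1 < ... < c_n bounding n contiguous area stages."""

    cuts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cuts) < 2:
            raise ValueError("need at least one interval")
        if self.cuts[0] != 0:
            raise ValueError("first cut point must be 0")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut points must be strictly increasing")

    @property
    def n_stages(self) -> int:
        return len(self.cuts) - 1


def build_stage_boundaries(final_area: float, n_stages: int = 12) -> StageBoundaries:
    """Evenly divide [0, final_area] into ``n_stages`` intervals.

    ``final_area`` is the averaged end-of-cycle (day-14) area of the
    reference crop; each stage spans final_area / n_stages cm^2.
    """
    if final_area <= 0:
        raise ValueError("final area must be positive")
    return StageBoundaries(tuple(np.linspace(0.0, final_area, n_stages + 1)))


def boundaries_from_series(reference: GrowthSeries, n_stages: int = 12) -> StageBoundaries:
    """Stage boundaries from a reference series' final daily-mean area."""
    daily = reference.daily_means()
    if not daily:
        raise ValueError("reference series is empty")
    return build_stage_boundaries(daily[-1][1], n_stages)


def assign_stage(area: float, boundaries: StageBoundaries) -> int:
    """Stage k (1-based) with area in [c_{k-1}, c_k); clamped to the top."""
    if area < 0:
        raise ValueError("area must be >= 0")
    k = int(np.searchsorted(boundaries.cuts, area, side="right"))
    return min(max(k, 1), boundaries.n_stages)


def growth_summary_frame(series_list: Sequence[GrowthSeries]):
    """Daily growth table: one row per (instance, view, day).

    Columns: instance, view, day, area (daily mean, cm^2), daily_rate (%
    change from the previous day; NaN on the first day or after a zero).
    """
    import pandas as pd

    rows = []
    for s in series_list:
        daily = s.daily_means()
        prev: Optional[float] = None
        for d, a in daily:
            rate = np.nan
            if prev is not None and prev > 0:
                rate = 100.0 * (a - prev) / prev
            rows.append({"instance": s.instance_id, "view": s.view,
                         "day": d, "area": a, "daily_rate": rate})
            prev = a
    return pd.DataFrame(rows)
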