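"""Parameter status classification and diurnal analytics.

Each of the six monitored parameters (pH, EC, water temperature, relative
humidity, air temperature, light intensity) has an acceptable range; a value
is classified with a three-colour traffic-light code: green inside the
range, yellow within 15% of the range width of either limit, red outside.
Light intensity has only a lower limit; its yellow band extends 15% of that
limit above it.

Diurnal analytics split sensor streams and growth series at the camera
day window (06:00-18:00 by default) into day/night means and day/night
growth rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, time
from typing import Iterable, Optional

import numpy as np

from .growth import GrowthSeries


@dataclass(frozen=True)
class ParameterRange:
    """Acceptable interval for one parameter; ``upper`` None = one-sided."""

    name: str
    lower: float
    upper: Optional[float] = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.upper is not None and not self.lower < self.upper:
            raise ValueError("lower must be < upper")


#: Reference acceptable ranges for the aquaponic grow bed.
DEFAULT_RANGES: dict[str, ParameterRange] = {
    "pH": ParameterRange("pH", 6.5, 7.0, "pH"),
    "EC": ParameterRange("EC", 100.0, 2000.0, "µS/cm"),
    "water_temp": ParameterRange("water_temp", 17.0, 30.0, "°C"),
    "RH": ParameterRange("RH", 50.0, 80.0, "%"),
    "air_temp": ParameterRange("air_temp", 22.0, 30.0, "°C"),
    "light": ParameterRange("light", 450.0, None, "lux"),
}


@dataclass(frozen=True)
class SensorReading:
    """One timestamped measurement of one monitored parameter."""

    parameter: str
    value: float
    timestamp: datetime
    units: str = ""
    source: str = "simulated"  # live | record | simulated

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("sensor value must be finite")


@dataclass(frozen=True)
class StatusReport:
    parameter: str
    value: float
    color: str  # green | yellow | red
    timestamp: Optional[datetime] = None


def classify_status(value: float, prange: ParameterRange,
                    band_fraction: float = 0.15) -> str:
    """Traffic-light colour of ``value`` against an acceptable range.

    Two-sided ranges: red outside [lower, upper]; yellow within
    ``band_fraction`` of the range width of either limit (inclusive);
    green in the middle. One-sided ranges (lower limit only): red below the
    limit, yellow in [lower, lower*(1+band_fraction)], green above.
    """
    if not 0 < band_fraction < 0.5:
        raise ValueError("band_fraction must be in (0, 0.5)")
    if prange.upper is None:
        if value < prange.lower:
            return "red"
        if value <= prange.lower * (1 + band_fraction):
            return "yellow"
        return "green"
    if value < prange.lower or value > prange.upper:
        return "red"
    band = band_fraction * (prange.upper - prange.lower)
    if value <= prange.lower + band or value >= prange.upper - band:
        return "yellow"
    return "green"


def _in_window(t: time, start: time, end: time) -> bool:
    if start <= end:
        return start <= t < end
    return t >= start or t < end  # window wrapping midnight


@dataclass
class DiurnalStat:
    """Day/night means of one parameter; missing windows are None."""

    parameter: str
    day_mean: Optional[float]
    night_mean: Optional[float]

    @property
    def difference(self) -> Optional[float]:
        if self.day_mean is None or self.night_mean is None:
            return None
        return abs(self.day_mean - self.night_mean)


def diurnal_stats(readings: Iterable[SensorReading],
                  day_start: time = time(6, 0),
                  day_end: time = time(18, 0)) -> dict[str, DiurnalStat]:
    """Per-parameter day/night means over a sensor stream.

    A reading is "day" when its clock time falls in [day_start, day_end).
    A window with no readings yields None for that mean (flagged missing,
    not an error).
    """
    day: dict[str, list[float]] = {}
    night: dict[str, list[float]] = {}
    for r in readings:
        bucket = day if _in_window(r.timestamp.time(), day_start, day_end) else night
        bucket.setdefault(r.parameter, []).append(r.value)
    out = {}
    for name in sorted(set(day) | set(night)):
        out[name] = DiurnalStat(
            name,
            float(np.mean(day[name])) if name in day else None,
            float(np.mean(night[name])) if name in night else None,
        )
    return out


@dataclass
class DayNightGrowth:
    """Mean relative growth (%) per daytime and per night-time period."""

    day_rate: Optional[float]
    night_rate: Optional[float]
    n_day_periods: int = 0
    n_night_periods: int = 0


def day_night_growth(series: GrowthSeries,
                     day_start: time = time(6, 0),
                     day_end: time = time(18, 0)) -> DayNightGrowth:
    """Split a growth series into daytime and overnight growth rates.

    Images exist only inside the day window, so the daytime rate of one day
    is the relative change from the first to the last same-day observation,
    and the night rate spans the last observation of a day to the first of
    the next. Periods with fewer than two bounding points are skipped; a
    side with no usable period reports None.
    """
    by_day: dict = {}
    for t, a in series.points:
        if _in_window(t.time(), day_start, day_end):
            by_day.setdefault(t.date(), []).append((t, a))
    days = sorted(by_day)
    day_rates = []
    for d in days:
        pts = by_day[d]
        if len(pts) < 2 or pts[0][1] == 0:
            continue
        day_rates.append(100.0 * (pts[-1][1] - pts[0][1]) / pts[0][1])
    night_rates = []
    for d0, d1 in zip(days, days[1:]):
        a_last = by_day[d0][-1][1]
        a_next = by_day[d1][0][1]
        if (d1 - d0).days != 1 or a_last == 0:
            continue
        night_rates.append(100.0 * (a_next - a_last) / a_last)
    return DayNightGrowth(
        float(np.mean(day_rates)) if day_rates else None,
        float(np.mean(night_rates)) if night_rates else None,
        len(day_rates), len(night_rates),
    )


def status_reports(readings: Iterable[SensorReading],
                   ranges: dict[str, ParameterRange] = DEFAULT_RANGES,
                   band_fraction: float = 0.15) -> list[StatusReport]:
    """Classify a batch of readings; unknown parameters raise KeyError."""
    out = []
    for r in readings:
        if r.parameter not in ranges:
            raise KeyError(f"no configured range for parameter {r.parameter!r}")
        out.append(StatusReport(r.parameter, r.value,
                                classify_status(r.value, ranges[r.parameter],
                                                band_fraction),
                                r.timestamp))
    return out
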