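"""Embedded record store and tick scheduler for the grow-bed twin.

The store mirrors the relational design of the original deployment —
``sensors_records``, ``masked_results``, ``accumulative_masked_records``,
``predictions`` and ``control_events`` — as an embedded in-memory store with
CSV round-tripping, replacing a networked SQL server. The accumulative
table reproduces the insert-trigger semantics of the original database: on
every masked-result insert, the per-(date, instance, view) means of area,
height, width and depth are recomputed, so the table is always a pure
function of ``masked_results`` and can be rebuilt from scratch at any time.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

from .clock import TwinClock
from .control import ControlEvent
from .growth import (FreshWeightModel, FeatureVector, GrowthSeries,
                     StageBoundaries, assign_stage, build_stage_boundaries,
                     growth_summary_frame, predict_fresh_weight)
from .monitor import (DEFAULT_RANGES, ParameterRange, SensorReading,
                      classify_status, diurnal_stats)
from .morphometrics import PlantFeatureRecord

logger = logging.getLogger(__name__)

TABLES = ("sensors_records", "masked_results", "accumulative_masked_records",
          "predictions", "control_events")

_ACC_FIELDS = ("area", "height", "width", "depth")


@dataclass
class RecordStore:
    """In-memory tables with uniqueness, ordering audit, and trigger logic."""

    sensors_records: list[dict] = field(default_factory=list)
    masked_results: list[dict] = field(default_factory=list)
    predictions: list[dict] = field(default_factory=list)
    control_events: list[dict] = field(default_factory=list)
    #: keyed (date, instance, view) -> row; maintained by on_masked_insert
    _accumulative: dict[tuple, dict] = field(default_factory=dict)
    _sensor_keys: set[tuple] = field(default_factory=set)
    out_of_order: list[tuple] = field(default_factory=list)

    # -- sensors -----------------------------------------------------------
    def insert_sensor_record(self, reading: SensorReading) -> bool:
        """Append a sensor reading; reject duplicate (timestamp, parameter).

        Returns True when inserted. Out-of-order timestamps are accepted
        but recorded in the ordering audit.
        """
        key = (reading.timestamp, reading.parameter)
        if key in self._sensor_keys:
            logger.warning("duplicate sensor record rejected: %s %s",
                           reading.parameter, reading.timestamp)
            return False
        if self.sensors_records and reading.timestamp < self.sensors_records[-1]["timestamp"]:
            self.out_of_order.append(key)
        self._sensor_keys.add(key)
        self.sensors_records.append({"timestamp": reading.timestamp,
                                     "parameter": reading.parameter,
                                     "value": reading.value})
        return True

    # -- masked results + accumulative trigger -----------------------------
    def on_masked_insert(self, record: PlantFeatureRecord, view: str) -> None:
        """Insert one view's features and refresh its accumulative group."""
        if view == "side":
            row = {"timestamp": record.timestamp, "instance": record.instance_id,
                   "view": "side", "area": record.area_side,
                   "height": record.height, "width": record.width,
                   "depth": np.nan,
                   "centroid_x": record.centroid_side[0],
                   "centroid_y": record.centroid_side[1]}
        elif view == "top":
            row = {"timestamp": record.timestamp, "instance": record.instance_id,
                   "view": "top", "area": record.area_top,
                   "height": np.nan, "width": np.nan, "depth": record.depth,
                   "centroid_x": record.centroid_top[0],
                   "centroid_y": record.centroid_top[1]}
        else:
            raise ValueError(f"unknown view {view!r}")
        self.masked_results.append(row)
        self._refresh_group(row["timestamp"].date(), row["instance"], view)

    def _refresh_group(self, day: date, instance: int, view: str) -> None:
        rows = [r for r in self.masked_results
                if r["timestamp"].date() == day and r["instance"] == instance
                and r["view"] == view]
        acc = {"date": day, "instance": instance, "view": view}
        for f in _ACC_FIELDS:
            vals = [r[f] for r in rows if not pd.isna(r[f])]
            acc[f] = float(np.mean(vals)) if vals else np.nan
        self._accumulative[(day, instance, view)] = acc

    def rebuild_accumulative(self) -> None:
        """Recompute the whole accumulative table from masked_results."""
        self._accumulative.clear()
        groups = {(r["timestamp"].date(), r["instance"], r["view"])
                  for r in self.masked_results}
        for day, instance, view in groups:
            self._refresh_group(day, instance, view)

    # -- other tables ------------------------------------------------------
    def insert_prediction(self, timestamp: datetime, instance: int,
                          growth_rate: Optional[float], fresh_weight: float,
                          stage: int) -> None:
        self.predictions.append({"timestamp": timestamp, "instance": instance,
                                 "growth_rate": growth_rate,
                                 "fresh_weight": fresh_weight, "stage": stage})

    def insert_control_event(self, event: ControlEvent) -> None:
        self.control_events.append({"timestamp": event.timestamp,
                                    "actuator": event.actuator,
                                    "command": event.command,
                                    "trigger": event.trigger,
                                    "reason": event.reason})

    # -- views -------------------------------------------------------------
    def to_frame(self, table: str) -> pd.DataFrame:
        if table == "accumulative_masked_records":
            rows = sorted(self._accumulative.values(),
                          key=lambda r: (r["date"], r["instance"], r["view"]))
            cols = ["date", "instance", "view", *_ACC_FIELDS]
        elif table == "sensors_records":
            rows, cols = self.sensors_records, ["timestamp", "parameter", "value"]
        elif table == "masked_results":
            rows = self.masked_results
            cols = ["timestamp", "instance", "view", "area", "height",
                    "width", "depth", "centroid_x", "centroid_y"]
        elif table == "predictions":
            rows = self.predictions
            cols = ["timestamp", "instance", "growth_rate", "fresh_weight", "stage"]
        elif table == "control_events":
            rows = self.control_events
            cols = ["timestamp", "actuator", "command", "trigger", "reason"]
        else:
            raise KeyError(table)
        return pd.DataFrame(list(rows), columns=cols)

    def growth_series(self, instance: int, view: str) -> GrowthSeries:
        """Record-level area series for one plant and view."""
        pts = sorted((r["timestamp"], r["area"]) for r in self.masked_results
                     if r["instance"] == instance and r["view"] == view)
        return GrowthSeries(instance, view, pts)

    def accumulative_series(self, instance: int, view: str) -> GrowthSeries:
        """Daily-mean area series from the accumulative table (noon-stamped)."""
        rows = sorted((k[0], v["area"]) for k, v in self._accumulative.items()
                      if k[1] == instance and k[2] == view)
        pts = [(datetime.combine(d, time(12, 0)), a) for d, a in rows]
        return GrowthSeries(instance, view, pts)

    @property
    def instances(self) -> list[int]:
        return sorted({r["instance"] for r in self.masked_results})

    # -- persistence -------------------------------------------------------
    def export_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for table in TABLES:
            self.to_frame(table).to_csv(directory / f"{table}.csv", index=False)

    def digest(self) -> str:
        """SHA-256 over all tables' CSV serialisations (order-stable)."""
        h = hashlib.sha256()
        for table in TABLES:
            buf = io.StringIO()
            self.to_frame(table).to_csv(buf, index=False)
            h.update(table.encode())
            h.update(buf.getvalue().encode())
        return h.hexdigest()


def import_csv(directory) -> RecordStore:
    """Rebuild a store from an export_csv directory."""
    directory = Path(directory)
    store = RecordStore()
    df = pd.read_csv(directory / "sensors_records.csv", parse_dates=["timestamp"])
    for r in df.itertuples(index=False):
        store.insert_sensor_record(SensorReading(r.parameter, r.value,
                                                 r.timestamp.to_pydatetime(),
                                                 source="record"))
    df = pd.read_csv(directory / "masked_results.csv", parse_dates=["timestamp"])
    for r in df.itertuples(index=False):
        ts = r.timestamp.to_pydatetime()
        if r.view == "side":
            rec = PlantFeatureRecord(int(r.instance), ts, area_side=r.area,
                                     height=r.height, width=r.width,
                                     centroid_side=(r.centroid_x, r.centroid_y))
        else:
            rec = PlantFeatureRecord(int(r.instance), ts, area_top=r.area,
                                     depth=r.depth,
                                     centroid_top=(r.centroid_x, r.centroid_y))
        store.on_masked_insert(rec, r.view)
    df = pd.read_csv(directory / "predictions.csv", parse_dates=["timestamp"])
    for r in df.itertuples(index=False):
        store.insert_prediction(r.timestamp.to_pydatetime(), int(r.instance),
                                None if pd.isna(r.growth_rate) else float(r.growth_rate),
                                float(r.fresh_weight), int(r.stage))
    df = pd.read_csv(directory / "control_events.csv", parse_dates=["timestamp"])
    for r in df.itertuples(index=False):
        store.insert_control_event(ControlEvent(r.timestamp.to_pydatetime(),
                                                r.actuator, r.command,
                                                r.trigger,
                                                "" if pd.isna(r.reason) else r.reason))
    return store


# -- scheduler --------------------------------------------------------------

@dataclass(frozen=True)
class ScheduledTask:
    """A cadence: fire every ``interval_seconds``, optionally gated to a
    daily clock window [window_start, window_end)."""

    name: str
    interval_seconds: int
    callback: Optional[Callable[[datetime], None]] = None
    window_start: Optional[time] = None
    window_end: Optional[time] = None

    def in_window(self, now: datetime) -> bool:
        if self.window_start is None:
            return True
        return self.window_start <= now.time() < self.window_end


def run_scheduler(clock: TwinClock,
                  tasks: Iterable[ScheduledTask]) -> list[tuple[datetime, str]]:
    """Drive tasks off the clock; each due tick fires exactly once.

    Returns the dispatch log as (timestamp, task name) pairs in firing
    order (time-major, then task declaration order).
    """
    tasks = list(tasks)
    for t in tasks:
        if t.interval_seconds % clock.tick_seconds != 0:
            raise ValueError(f"task {t.name!r} interval is not a multiple of "
                             "the clock tick")
    log: list[tuple[datetime, str]] = []
    for elapsed, now in clock:
        for task in tasks:
            if clock.due(elapsed, task.interval_seconds) and task.in_window(now):
                if task.callback is not None:
                    task.callback(now)
                log.append((now, task.name))
    return log


# -- reports ----------------------------------------------------------------

def query_report(store: RecordStore, kind: str,
                 instance: Optional[int] = None,
                 parameter: Optional[str] = None,
                 ranges: dict[str, ParameterRange] = DEFAULT_RANGES,
                 band_fraction: float = 0.15,
                 model: FreshWeightModel = FreshWeightModel(),
                 boundaries: Optional[StageBoundaries] = None,
                 day_start: time = time(6, 0),
                 day_end: time = time(18, 0)) -> pd.DataFrame:
    """Read-only tabular report over the store.

    kind="status": latest value and traffic-light colour per parameter.
    kind="growth": per (instance, view, day) area and daily rate, plus
        per-(instance, day) fresh weight and stage where both views exist.
    kind="diurnal": day/night means and difference per parameter.
    kind="events": the control-event log.
    """
    if kind == "status":
        rows = []
        latest: dict[str, dict] = {}
        for r in store.sensors_records:
            cur = latest.get(r["parameter"])
            if cur is None or r["timestamp"] >= cur["timestamp"]:
                latest[r["parameter"]] = r
        for name in sorted(latest):
            if parameter is not None and name != parameter:
                continue
            r = latest[name]
            color = (classify_status(r["value"], ranges[name], band_fraction)
                     if name in ranges else "unknown")
            rows.append({"parameter": name, "timestamp": r["timestamp"],
                         "value": r["value"], "color": color})
        return pd.DataFrame(rows, columns=["parameter", "timestamp", "value",
                                           "color"])
    if kind == "growth":
        instances = [instance] if instance is not None else store.instances
        series = [store.accumulative_series(i, v)
                  for i in instances for v in ("side", "top")]
        series = [s for s in series if s.points]
        df = growth_summary_frame(series)
        if df.empty:
            return pd.DataFrame(columns=["instance", "view", "day", "area",
                                         "daily_rate", "fresh_weight", "stage"])
        if boundaries is None:
            boundaries = build_stage_boundaries(12.0, 12)
        acc = store.to_frame("accumulative_masked_records")
        extras = []
        for (inst, day), g in acc.groupby(["instance", "day" if "day" in acc else "date"]):
            side = g[g["view"] == "side"]
            top = g[g["view"] == "top"]
            if side.empty or top.empty:
                continue
            fv = FeatureVector(height=float(side["height"].iloc[0]),
                               depth=float(top["depth"].iloc[0]),
                               width=float(side["width"].iloc[0]),
                               side_area=float(side["area"].iloc[0]),
                               top_area=float(top["area"].iloc[0]))
            extras.append({"instance": inst, "day": day,
                           "fresh_weight": predict_fresh_weight(fv, model),
                           "stage": assign_stage(float(side["area"].iloc[0]),
                                                 boundaries)})
        if extras:
            df = df.merge(pd.DataFrame(extras), on=["instance", "day"],
                          how="left")
        return df
    if kind == "diurnal":
        readings = [SensorReading(r["parameter"], r["value"], r["timestamp"],
                                  source="record")
                    for r in store.sensors_records
                    if parameter is None or r["parameter"] == parameter]
        stats = diurnal_stats(readings, day_start, day_end)
        return pd.DataFrame([{"parameter": s.parameter, "day_mean": s.day_mean,
                              "night_mean": s.night_mean,
                              "difference": s.difference}
                             for s in stats.values()],
                            columns=["parameter", "day_mean", "night_mean",
                                     "difference"])
    if kind == "events":
        df = store.to_frame("control_events")
        return df
    raise ValueError(f"unknown report kind {kind!r}")
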