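"""Record store trigger semantics, scheduler cadences, reports, round trips."""

from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest

from hydrotwin.clock import TwinClock
from hydrotwin.control import ControlEvent
from hydrotwin.monitor import SensorReading
from hydrotwin.morphometrics import PlantFeatureRecord
from hydrotwin.store import (RecordStore, ScheduledTask, import_csv,
                             query_report, run_scheduler)

T0 = datetime(2022, 6, 1, 8, 0)


def side_record(instance, ts, area, height=2.0, width=3.0):
    return PlantFeatureRecord(instance, ts, area_side=area, height=height,
                              width=width, centroid_side=(1.0, 1.0))


class TestSensorInserts:
    def test_insert_increments_count(self):
        store = RecordStore()
        assert store.insert_sensor_record(SensorReading("pH", 7.0, T0))
        assert len(store.sensors_records) == 1

    def test_duplicate_key_rejected(self):
        store = RecordStore()
        store.insert_sensor_record(SensorReading("pH", 7.0, T0))
        assert not store.insert_sensor_record(SensorReading("pH", 7.1, T0))
        assert len(store.sensors_records) == 1
        # same timestamp, different parameter is fine
        assert store.insert_sensor_record(SensorReading("EC", 900.0, T0))

    def test_out_of_order_accepted_but_flagged(self):
        store = RecordStore()
        store.insert_sensor_record(SensorReading("pH", 7.0, T0))
        earlier = T0 - timedelta(minutes=5)
        assert store.insert_sensor_record(SensorReading("pH", 6.9, earlier))
        assert store.out_of_order == [(earlier, "pH")]


class TestAccumulativeTrigger:
    def test_same_group_mean(self):
        store = RecordStore()
        store.on_masked_insert(side_record(1, T0, 4.0), "side")
        store.on_masked_insert(side_record(1, T0 + timedelta(hours=1), 6.0),
                               "side")
        acc = store.to_frame("accumulative_masked_records")
        assert len(acc) == 1
        assert acc["area"].iloc[0] == 5.0

    def test_two_dates_two_rows(self):
        store = RecordStore()
        store.on_masked_insert(side_record(1, T0, 4.0), "side")
        store.on_masked_insert(side_record(1, T0 + timedelta(days=1), 6.0),
                               "side")
        assert len(store.to_frame("accumulative_masked_records")) == 2

    def test_randomized_batch_equals_groupby_oracle(self, rng):
        store = RecordStore()
        rows = []
        for _ in range(200):
            inst = int(rng.integers(1, 4))
            day = int(rng.integers(0, 3))
            hour = int(rng.integers(6, 18))
            ts = T0.replace(hour=hour) + timedelta(days=day)
            area = float(rng.uniform(1, 20))
            store.on_masked_insert(side_record(inst, ts, area), "side")
            rows.append({"date": ts.date(), "instance": inst, "area": area})
        oracle = (pd.DataFrame(rows)
                  .groupby(["date", "instance"])["area"].mean()
                  .reset_index()
                  .sort_values(["date", "instance"]))
        acc = (store.to_frame("accumulative_masked_records")
               [["date", "instance", "area"]]
               .sort_values(["date", "instance"]))
        np.testing.assert_allclose(acc["area"].to_numpy(),
                                   oracle["area"].to_numpy())

    def test_rebuild_is_byte_identical(self, rng):
        store = RecordStore()
        for k in range(60):
            ts = T0 + timedelta(hours=int(rng.integers(0, 72)), minutes=k)
            store.on_masked_insert(side_record(int(rng.integers(1, 3)), ts,
                                               float(rng.uniform(1, 9))),
                                   "side")
        before = store.to_frame("accumulative_masked_records").to_csv()
        store.rebuild_accumulative()
        after = store.to_frame("accumulative_masked_records").to_csv()
        assert before == after


class TestScheduler:
    def test_one_hour_counts_match_floor_division(self):
        clock = TwinClock(T0, T0 + timedelta(hours=1), tick_seconds=1)
        log = run_scheduler(clock, [ScheduledTask("record", 300),
                                    ScheduledTask("imaging", 1800)])
        names = [n for _, n in log]
        assert names.count("record") == 3600 // 300 == 12
        assert names.count("imaging") == 3600 // 1800 == 2

    def test_display_tick_fires_every_second(self):
        clock = TwinClock(T0, T0 + timedelta(seconds=30), tick_seconds=1)
        log = run_scheduler(clock, [ScheduledTask("display", 1)])
        assert len(log) == 30

    def test_camera_window_gates_imaging(self):
        start = datetime(2022, 6, 1, 0, 0)
        clock = TwinClock(start, start + timedelta(days=1), tick_seconds=60)
        log = run_scheduler(clock, [
            ScheduledTask("imaging", 1800, window_start=time(6, 0),
                          window_end=time(18, 0))])
        assert len(log) == 24
        assert all(6 <= ts.hour < 18 for ts, _ in log)

    def test_full_day_record_count(self):
        clock = TwinClock(T0, T0 + timedelta(days=1), tick_seconds=60)
        log = run_scheduler(clock, [ScheduledTask("record", 300)])
        assert len(log) == 288

    def test_stalled_clock_fires_nothing(self):
        clock = TwinClock(T0, T0, tick_seconds=1)
        assert run_scheduler(clock, [ScheduledTask("record", 300)]) == []

    def test_callbacks_invoked_with_due_instant(self):
        seen = []
        clock = TwinClock(T0, T0 + timedelta(minutes=10), tick_seconds=60)
        run_scheduler(clock, [ScheduledTask("record", 300, seen.append)])
        assert seen == [T0 + timedelta(minutes=5), T0 + timedelta(minutes=10)]

    def test_incompatible_tick_rejected(self):
        clock = TwinClock(T0, T0 + timedelta(minutes=10), tick_seconds=7)
        with pytest.raises(ValueError):
            run_scheduler(clock, [ScheduledTask("record", 300)])


class TestReportsAndRoundTrip:
    def test_empty_store_reports_empty_no_error(self):
        store = RecordStore()
        for kind in ("status", "growth", "diurnal", "events"):
            assert len(query_report(store, kind)) == 0

    def test_status_report_classifies_latest(self):
        store = RecordStore()
        store.insert_sensor_record(SensorReading("RH", 65.0, T0))
        store.insert_sensor_record(
            SensorReading("RH", 85.0, T0 + timedelta(minutes=5)))
        df = query_report(store, "status")
        assert df.loc[df.parameter == "RH", "color"].item() == "red"
        assert df.loc[df.parameter == "RH", "value"].item() == 85.0

    def test_growth_report_filter_by_instance(self, short_run):
        df = query_report(short_run.store, "growth", instance=2)
        assert set(df["instance"]) == {2}
        assert {"area", "daily_rate", "fresh_weight", "stage"} <= set(df.columns)

    def test_diurnal_report_totals_equal_direct_aggregation(self, short_run):
        df = query_report(short_run.store, "diurnal")
        ph = df[df.parameter == "pH"].iloc[0]
        rows = [r for r in short_run.store.sensors_records
                if r["parameter"] == "pH"]
        day = [r["value"] for r in rows if 6 <= r["timestamp"].hour < 18]
        assert ph["day_mean"] == pytest.approx(np.mean(day))

    def test_csv_round_trip_preserves_tables(self, short_run, tmp_path):
        short_run.store.export_csv(tmp_path)
        back = import_csv(tmp_path)
        for table in ("sensors_records", "masked_results",
                      "accumulative_masked_records", "control_events"):
            a = short_run.store.to_frame(table)
            b = back.to_frame(table)
            assert len(a) == len(b)
        orig = short_run.store.to_frame("sensors_records")
        new = back.to_frame("sensors_records")
        np.testing.assert_allclose(orig["value"].to_numpy(),
                                   new["value"].to_numpy())
        assert list(orig["timestamp"]) == list(new["timestamp"])
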