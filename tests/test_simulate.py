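"""The virtual grow bed: sensor streams, trajectories, masks, closed loop."""

import dataclasses
from datetime import datetime, timedelta

import numpy as np
import pytest

from hydrotwin.config import (CameraConfig, DiurnalProfile, PlantSpec,
                              RHDynamics, SimConfig)
from hydrotwin.growth import daily_growth_rate
from hydrotwin.morphometrics import (extract_side_features,
                                     extract_top_features)
from hydrotwin.simulate import (closed_loop_run, imaging_epochs,
                                plant_geometry, render_masks,
                                render_view_image, simulate_plants,
                                simulate_sensors, _extents_from_area)

START = datetime(2022, 6, 1)


def one_day_config(**kw):
    return SimConfig(duration_days=1, **kw)


class TestSimulateSensors:
    def test_flat_profile_gives_constant_stream(self):
        cfg = one_day_config(profiles={
            "pH": DiurnalProfile(7.0, 7.0), "EC": DiurnalProfile(1000, 1000),
            "water_temp": DiurnalProfile(20, 20),
            "air_temp": DiurnalProfile(25, 25),
            "light": DiurnalProfile(500, 500)})
        values = {r.value for r in simulate_sensors(cfg) if r.parameter == "pH"}
        assert values == {7.0}

    def test_two_level_profile_switches_at_day_window(self):
        readings = [r for r in simulate_sensors(SimConfig(duration_days=1))
                    if r.parameter == "pH"]
        for r in readings:
            expected = 6.9 if 6 <= r.timestamp.hour < 18 else 7.05
            assert r.value == expected

    def test_same_seed_is_bit_identical(self):
        noisy = {"pH": DiurnalProfile(6.9, 7.05, noise_sd=0.05)}
        cfg = one_day_config(profiles={**SimConfig().profiles, **noisy}, seed=3)
        a = simulate_sensors(cfg)
        b = simulate_sensors(cfg)
        assert a == b
        c = simulate_sensors(dataclasses.replace(cfg, seed=4))
        assert a != c

    def test_record_count_per_day(self):
        readings = simulate_sensors(SimConfig(duration_days=1))
        per_param = sum(1 for r in readings if r.parameter == "RH")
        assert per_param == 288  # 24 h at 5-min records

    def test_rh_relaxes_monotonically_toward_ceiling(self):
        cfg = one_day_config(rh=RHDynamics(initial=60.0, ceiling=90.0))
        rhs = [r.value for r in simulate_sensors(cfg, humidifier_on=True)
               if r.parameter == "RH"]
        assert all(a < b for a, b in zip(rhs[:48], rhs[1:49]))
        assert all(a <= b for a, b in zip(rhs, rhs[1:]))  # saturates at float eps
        assert all(v <= 90.0 for v in rhs)
        # closed-form first-order response after 1 h (12 one-minute steps)
        tau = cfg.rh.tau_rise_min
        expected = 90.0 - (90.0 - 60.0) * np.exp(-60.0 / tau)
        assert rhs[11] == pytest.approx(expected, rel=1e-6)


class TestSimulatePlants:
    def test_zero_rate_is_constant(self):
        cfg = one_day_config(plants=(PlantSpec(side_rate=0, top_rate=0),))
        traj = simulate_plants(cfg)
        areas = {p.area for p in traj[(1, "side")]}
        assert areas == {2.0}

    def test_fourteen_day_closed_form(self):
        cfg = SimConfig(duration_days=15,
                        plants=(PlantSpec(initial_side_area=1.0, side_rate=15),))
        start = datetime.fromisoformat(cfg.start_date)
        pt = plant_geometry(cfg.plants[0], 1, "side",
                            start + timedelta(days=14), start, cfg.camera)
        assert pt.area == pytest.approx(1.15 ** 14)
        assert pt.area == pytest.approx(7.0757, abs=5e-4)

    def test_trajectory_recovers_configured_rates_exactly(self):
        cfg = SimConfig(duration_days=4)
        traj = simulate_plants(cfg)
        for i, spec in enumerate(cfg.plants, start=1):
            from hydrotwin.growth import GrowthSeries
            s = GrowthSeries(i, "side",
                             [(p.timestamp, p.area) for p in traj[(i, "side")]])
            assert daily_growth_rate(s).mean_rate == pytest.approx(
                spec.side_rate, abs=1e-9)

    def test_extents_consistent_with_ellipse_area(self):
        w, h = _extents_from_area(10.0, 0.8)
        assert np.pi / 4 * w * h == pytest.approx(10.0)
        assert h / w == pytest.approx(0.8)


class TestRenderMasks:
    def make_points(self, area, cam):
        w, h = _extents_from_area(area, cam.side_aspect)
        wt, d = _extents_from_area(area, cam.top_aspect)
        from hydrotwin.simulate import TrajectoryPoint
        t = datetime(2022, 6, 1, 12)
        return (TrajectoryPoint(t, 1, "side", area, w, h),
                TrajectoryPoint(t, 1, "top", area, wt, d))

    @pytest.mark.parametrize("area", [1.0, 5.0, 14.0])
    def test_pixel_area_within_5_percent(self, area):
        cam = CameraConfig()
        sp, tp = self.make_points(area, cam)
        sm, tm = render_masks(sp, tp, cam)
        assert sm.pixels.sum() * cam.scale_cm_per_px ** 2 == pytest.approx(
            area, rel=0.05)
        assert tm.pixels.sum() * cam.scale_cm_per_px ** 2 == pytest.approx(
            area, rel=0.05)

    def test_extents_within_one_pixel(self):
        cam = CameraConfig()
        sp, tp = self.make_points(8.0, cam)
        sm, tm = render_masks(sp, tp, cam)
        f = extract_side_features(sm)
        tol = cam.scale_cm_per_px
        assert abs(f.height - sp.extent_other) <= tol
        assert abs(f.width - sp.extent_width) <= tol
        assert abs(extract_top_features(tm).depth - tp.extent_other) <= tol

    def test_degenerate_tiny_plant_has_foreground(self):
        cam = CameraConfig()
        sp, tp = self.make_points(0.001, cam)
        sm, _ = render_masks(sp, tp, cam)
        assert sm.pixels.sum() >= 1

    def test_doubling_extents_doubles_bounding_box(self):
        cam = CameraConfig()
        sp, _ = self.make_points(4.0, cam)
        sp2 = dataclasses.replace(sp, extent_width=2 * sp.extent_width,
                                  extent_other=2 * sp.extent_other)
        img1 = render_view_image([sp], cam)
        img2 = render_view_image([sp2], cam)
        rows1 = np.ptp(np.nonzero(img1)[0]) + 1
        rows2 = np.ptp(np.nonzero(img2)[0]) + 1
        assert rows2 == pytest.approx(2 * rows1, abs=2)


class TestImagingSchedule:
    def test_24_epochs_per_day(self):
        epochs = imaging_epochs(SimConfig(duration_days=1))
        assert len(epochs) == 24
        assert epochs[0].time().hour == 6
        assert epochs[-1].strftime("%H:%M") == "17:30"

    def test_all_epochs_inside_window(self):
        for e in imaging_epochs(SimConfig(duration_days=3)):
            assert 6 <= e.hour < 18


class TestClosedLoop:
    def test_one_day_record_and_feature_counts(self, short_run):
        st = short_run.store
        assert len(st.sensors_records) == 288 * 6
        # conservation: plants x epochs per view
        assert len(st.masked_results) == 3 * 24 * 2
        assert len(st.predictions) == 3 * 24

    def test_rerun_same_seed_identical_digest(self, short_run):
        again = closed_loop_run(SimConfig(duration_days=1))
        assert again.store.digest() == short_run.store.digest()

    def test_imaging_rows_only_in_camera_window(self, short_run):
        for r in short_run.store.masked_results:
            assert 6 <= r["timestamp"].hour < 18

    def test_full_stack_rate_recovery_within_pixelization(self):
        """Pipeline-reported daily growth equals the generating rate."""
        cfg = SimConfig(duration_days=5)
        res = closed_loop_run(cfg)
        for i, spec in enumerate(cfg.plants, start=1):
            side = daily_growth_rate(res.store.accumulative_series(i, "side"))
            top = daily_growth_rate(res.store.accumulative_series(i, "top"))
            assert side.mean_rate == pytest.approx(spec.side_rate, abs=1.0)
            assert top.mean_rate == pytest.approx(spec.top_rate, abs=1.0)

    def test_manual_override_appears_in_event_log(self):
        when = datetime(2022, 6, 1, 10, 0)
        res = closed_loop_run(SimConfig(duration_days=1),
                              overrides=[(when, "ring_light", "turn_on")])
        manual = [e for e in res.events if e.trigger == "manual"]
        assert len(manual) == 1
        assert manual[0].actuator == "ring_light"
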