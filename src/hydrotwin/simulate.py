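"""Virtual grow bed: seeded sensor streams, plant trajectories, rendered
masks, and the closed physical<->virtual loop.

The simulator stands in for the physical environment. Water and air
parameters follow two-level day/night profiles with optional Gaussian
noise; relative humidity instead obeys first-order relaxation toward the
humidifier ceiling (actuator on) or the ambient diurnal profile (off), so
the feedback controller has real dynamics to act against. Plants grow
geometrically per view at configured daily rates; silhouettes are rasterised
as ellipses whose pixel area and bounding box track the generating
trajectory, which lets the full imaging->segmentation->morphometrics->
prediction pipeline run end-to-end and be checked against the ground truth
it was generated from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from skimage import draw

from .clock import TICK_PREDICT_S, TICK_RECORD_S
from .config import CameraConfig, PlantSpec, SimConfig
from .control import Controller, ActuatorState
from .growth import (FeatureVector, FreshWeightModel, build_stage_boundaries,
                     assign_stage, daily_growth_rate, overall_growth_rate,
                     predict_fresh_weight)
from .monitor import SensorReading
from .morphometrics import (PlantFeatureRecord, ViewMask,
                            extract_side_features, extract_top_features,
                            segment_synthetic)
from .store import RecordStore

_PARAM_ORDER = ("pH", "EC", "water_temp", "air_temp", "light")
_RH_STREAM_INDEX = len(_PARAM_ORDER)
_PLANT_STREAM_BASE = 16


def _start_datetime(config: SimConfig) -> datetime:
    return datetime.fromisoformat(config.start_date)


def _is_day(t: time, config: SimConfig) -> bool:
    return config.day_start <= t < config.day_end


@dataclass(frozen=True)
class TrajectoryPoint:
    """Ground-truth geometry of one plant in one view at one instant."""

    timestamp: datetime
    instance_id: int
    view: str
    area: float           # cm^2
    extent_width: float   # cm, along image columns
    extent_other: float   # cm: height (side) or depth (top), along rows


def _extents_from_area(area: float, aspect: float) -> tuple[float, float]:
    # Ellipse: area = pi/4 * width * other, with other = aspect * width.
    width = math.sqrt(4.0 * area / (math.pi * aspect))
    return width, aspect * width


def imaging_epochs(config: SimConfig) -> list[datetime]:
    """Imaging instants: every imaging interval inside [day_start, day_end)."""
    start = _start_datetime(config)
    total_s = config.duration_days * 86400
    step_s = config.imaging_interval_min * 60
    out = []
    for elapsed in range(step_s, total_s + 1, step_s):
        now = start + timedelta(seconds=elapsed)
        if _is_day(now.time(), config):
            out.append(now)
    return out


def plant_geometry(spec: PlantSpec, instance_id: int, view: str,
                   now: datetime, start: datetime,
                   camera: CameraConfig,
                   noise: float = 1.0) -> TrajectoryPoint:
    """Ground-truth trajectory point for one plant/view at ``now``.

    Area grows geometrically: A(t) = A0 * (1 + rate/100)^(t days); extents
    scale as sqrt(area) at the view's configured aspect ratio.
    """
    days = (now - start).total_seconds() / 86400.0
    if view == "side":
        a0, rate, aspect = spec.initial_side_area, spec.side_rate, camera.side_aspect
    else:
        a0, rate, aspect = spec.initial_top_area, spec.top_rate, camera.top_aspect
    area = a0 * (1.0 + rate / 100.0) ** days * noise
    width, other = _extents_from_area(area, aspect)
    return TrajectoryPoint(now, instance_id, view, area, width, other)


def simulate_plants(config: SimConfig,
                    epochs: Optional[Sequence[datetime]] = None
                    ) -> dict[tuple[int, str], list[TrajectoryPoint]]:
    """Per-plant, per-view trajectories sampled at the imaging epochs."""
    if epochs is None:
        epochs = imaging_epochs(config)
    start = _start_datetime(config)
    out: dict[tuple[int, str], list[TrajectoryPoint]] = {}
    for i, spec in enumerate(config.plants, start=1):
        for view in ("side", "top"):
            rng = np.random.default_rng(
                [config.seed, _PLANT_STREAM_BASE + i,
                 0 if view == "side" else 1])
            pts = []
            for now in epochs:
                noise = (float(np.exp(rng.normal(0.0, spec.growth_noise_sd)))
                         if spec.growth_noise_sd > 0 else 1.0)
                pts.append(plant_geometry(spec, i, view, now, start,
                                          config.camera, noise))
            out[(i, view)] = pts
    return out


def render_view_image(points: Sequence[TrajectoryPoint],
                      camera: CameraConfig) -> np.ndarray:
    """Rasterise one view's plants as bright ellipses on a dark canvas.

    Plants are laid out left-to-right in instance order at evenly spaced
    column centres, so connected-component segmentation recovers the
    original instance numbering.
    """
    nrows, ncols = camera.image_shape
    img = np.zeros((nrows, ncols), dtype=np.uint8)
    n = len(points)
    for k, pt in enumerate(sorted(points, key=lambda p: p.instance_id)):
        c_center = (k + 0.5) * ncols / n
        r_center = nrows / 2.0
        r_radius = pt.extent_other / 2.0 / camera.scale_cm_per_px
        c_radius = pt.extent_width / 2.0 / camera.scale_cm_per_px
        rr, cc = draw.ellipse(r_center, c_center, max(r_radius, 0.6),
                              max(c_radius, 0.6), shape=img.shape)
        img[rr, cc] = 255
    return img


def render_masks(side_point: TrajectoryPoint, top_point: TrajectoryPoint,
                 camera: CameraConfig) -> tuple[ViewMask, ViewMask]:
    """Single-plant masks for both views at one trajectory instant."""
    masks = []
    for pt in (side_point, top_point):
        img = render_view_image([pt], camera)
        masks.append(ViewMask(img > 0, view=pt.view,
                              scale=camera.scale_cm_per_px,
                              instance_id=pt.instance_id,
                              timestamp=pt.timestamp))
    return masks[0], masks[1]


def _profile_level(config: SimConfig, name: str, now: datetime) -> float:
    prof = config.profiles[name]
    return prof.day_level if _is_day(now.time(), config) else prof.night_level


class RHModel:
    """First-order RH response stepped at fixed substeps."""

    def __init__(self, config: SimConfig):
        self._cfg = config.rh
        self._sim = config
        self.rh = config.rh.initial

    def ambient(self, now: datetime) -> float:
        return (self._cfg.ambient_day if _is_day(now.time(), self._sim)
                else self._cfg.ambient_night)

    def step(self, now: datetime, humidifier_on: bool,
             dt_minutes: float = 1.0) -> float:
        if humidifier_on:
            target, tau = self._cfg.ceiling, self._cfg.tau_rise_min
        else:
            target, tau = self.ambient(now), self._cfg.tau_decay_min
        self.rh += (target - self.rh) * (1.0 - math.exp(-dt_minutes / tau))
        return self.rh


def simulate_sensors(config: SimConfig,
                     humidifier_on: Callable[[datetime], bool] | bool = False
                     ) -> list[SensorReading]:
    """Open-loop sensor stream at the record interval over the full run.

    ``humidifier_on`` is the actuator trace driving the RH dynamics: a
    constant or a callable of the current instant. Identical (config, seed)
    give bit-identical streams.
    """
    trace = humidifier_on if callable(humidifier_on) else (lambda _t: humidifier_on)
    start = _start_datetime(config)
    total_s = config.duration_days * 86400
    step_s = config.record_interval_min * 60
    rngs = {name: np.random.default_rng([config.seed, i])
            for i, name in enumerate(_PARAM_ORDER)}
    rh_rng = np.random.default_rng([config.seed, _RH_STREAM_INDEX])
    rh_model = RHModel(config)
    readings: list[SensorReading] = []
    now = start
    for elapsed in range(60, total_s + 1, 60):
        now = start + timedelta(seconds=elapsed)
        rh_model.step(now, trace(now))
        if elapsed % step_s != 0:
            continue
        for name in _PARAM_ORDER:
            prof = config.profiles[name]
            value = _profile_level(config, name, now)
            if prof.noise_sd > 0:
                value += float(rngs[name].normal(0.0, prof.noise_sd))
            readings.append(SensorReading(name, value, now, prof.units))
        rh_val = rh_model.rh
        if config.rh.noise_sd > 0:
            rh_val += float(rh_rng.normal(0.0, config.rh.noise_sd))
        readings.append(SensorReading("RH", rh_val, now, "%"))
    return readings


@dataclass
class TwinRunResult:
    """Everything a closed-loop run produced."""

    config: SimConfig
    store: RecordStore
    controller: Controller
    rh_trace: list[tuple[datetime, float]] = field(default_factory=list)

    @property
    def events(self):
        return self.controller.events


def closed_loop_run(config: SimConfig,
                    overrides: Sequence[tuple[datetime, str, str]] = (),
                    masks_dir: Optional[str] = None) -> TwinRunResult:
    """Run the full twin: sensing, records, imaging, prediction, control.

    The simulated clock drives three cadences: sensor sampling and record
    insertion every ``record_interval_min``, imaging + morphometrics +
    prediction every ``imaging_interval_min`` inside the camera day window,
    and a control cycle after every record insertion whose humidifier
    commands feed back into the RH dynamics. ``overrides`` are manual
    (timestamp, actuator, command) interventions applied at their due time.
    Fully reproducible from (config, seed).
    """
    start = _start_datetime(config)
    total_min = config.duration_days * 24 * 60
    record_min = config.record_interval_min
    imaging_min = config.imaging_interval_min

    store = RecordStore()
    controller = Controller(
        config.control,
        state=ActuatorState(humidifier=config.rh.initial_humidifier_on))
    rh_model = RHModel(config)
    rngs = {name: np.random.default_rng([config.seed, i])
            for i, name in enumerate(_PARAM_ORDER)}
    rh_rng = np.random.default_rng([config.seed, _RH_STREAM_INDEX])
    plant_rngs = {
        (i, view): np.random.default_rng(
            [config.seed, _PLANT_STREAM_BASE + i, 0 if view == "side" else 1])
        for i in range(1, len(config.plants) + 1) for view in ("side", "top")}
    boundaries = build_stage_boundaries(config.stages.reference_final_area,
                                        config.stages.n_stages)
    fw_model = FreshWeightModel()
    pending = sorted(overrides)
    rh_trace: list[tuple[datetime, float]] = []
    if masks_dir is not None:
        Path(masks_dir).mkdir(parents=True, exist_ok=True)

    for elapsed_min in range(1, total_min + 1):
        now = start + timedelta(minutes=elapsed_min)
        rh_model.step(now, controller.state.humidifier)
        rh_trace.append((now, rh_model.rh))

        while pending and pending[0][0] <= now:
            _, actuator, command = pending.pop(0)
            controller.manual_override(actuator, command, now)

        if elapsed_min % record_min == 0:
            readings = []
            for name in _PARAM_ORDER:
                prof = config.profiles[name]
                value = _profile_level(config, name, now)
                if prof.noise_sd > 0:
                    value += float(rngs[name].normal(0.0, prof.noise_sd))
                readings.append(SensorReading(name, value, now, prof.units))
            rh_val = rh_model.rh
            if config.rh.noise_sd > 0:
                rh_val += float(rh_rng.normal(0.0, config.rh.noise_sd))
            readings.append(SensorReading("RH", rh_val, now, "%"))
            for r in readings:
                store.insert_sensor_record(r)
            _, events, _ = controller.process_cycle(readings, now)
            for ev in events:
                store.insert_control_event(ev)

        if elapsed_min % imaging_min == 0 and _is_day(now.time(), config):
            _imaging_cycle(config, store, now, start, plant_rngs, boundaries,
                           fw_model, masks_dir)

    return TwinRunResult(config, store, controller, rh_trace)


def _imaging_cycle(config: SimConfig, store: RecordStore, now: datetime,
                   start: datetime, plant_rngs, boundaries, fw_model,
                   masks_dir) -> None:
    per_view_records: dict[str, dict[int, PlantFeatureRecord]] = {}
    for view in ("side", "top"):
        points = []
        for i, spec in enumerate(config.plants, start=1):
            rng = plant_rngs[(i, view)]
            noise = (float(np.exp(rng.normal(0.0, spec.growth_noise_sd)))
                     if spec.growth_noise_sd > 0 else 1.0)
            points.append(plant_geometry(spec, i, view, now, start,
                                         config.camera, noise))
        img = render_view_image(points, config.camera)
        if masks_dir is not None:
            from PIL import Image
            stamp = now.strftime("%Y%m%dT%H%M")
            Image.fromarray(img).save(Path(masks_dir) / f"{view}_{stamp}.png")
        masks = segment_synthetic(img, view, config.camera.scale_cm_per_px,
                                  timestamp=now)
        recs = {}
        for mask in masks:
            rec = (extract_side_features(mask) if view == "side"
                   else extract_top_features(mask))
            store.on_masked_insert(rec, view)
            recs[mask.instance_id] = rec
        per_view_records[view] = recs

    for i in store.instances:
        side = per_view_records.get("side", {}).get(i)
        top = per_view_records.get("top", {}).get(i)
        if side is None or top is None:
            continue
        rate = None
        try:
            side_rate = daily_growth_rate(store.accumulative_series(i, "side"))
            top_rate = daily_growth_rate(store.accumulative_series(i, "top"))
            rate = overall_growth_rate(side_rate.mean_rate, top_rate.mean_rate)
        except ValueError:
            pass  # fewer than two days of records so far
        fv = FeatureVector(height=side.height, depth=top.depth,
                           width=side.width, side_area=side.area_side,
                           top_area=top.area_top)
        weight = predict_fresh_weight(fv, fw_model)
        stage = assign_stage(side.area_side, boundaries)
        store.insert_prediction(now, i, rate, weight, stage)


def piecewise_diurnal_series(day_factor: float, night_factor: float,
                             n_days: int = 5, initial_area: float = 1.0,
                             start: datetime = datetime(2022, 6, 1),
                             day_start: time = time(6, 0),
                             day_end: time = time(18, 0),
                             interval_min: int = 30):
    """Noiseless area series growing by ``day_factor`` over each imaging day
    and ``night_factor`` overnight, sampled at the imaging schedule.

    Within a day the factor is spread geometrically over the intervals
    between consecutive epochs, so the first-to-last same-day ratio is
    exactly ``day_factor``; the last epoch of a day to the first of the next
    applies ``night_factor``.
    """
    from .growth import GrowthSeries

    epochs_per_day = []
    t = datetime.combine(start.date(), day_start)
    while t.time() < day_end:
        epochs_per_day.append(t.time())
        t += timedelta(minutes=interval_min)
    n_epochs = len(epochs_per_day)
    step_factor = day_factor ** (1.0 / (n_epochs - 1))
    points = []
    area = initial_area
    for d in range(n_days):
        day = start.date() + timedelta(days=d)
        for k, tt in enumerate(epochs_per_day):
            if k > 0:
                area *= step_factor
            points.append((datetime.combine(day, tt), area))
        area *= night_factor
    return GrowthSeries(1, "combined", points)
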