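"""Configuration for the grow-bed twin.

All defaults describe the reference desk-scale setup: a 14-day lettuce cycle
in an NFT channel, six monitored water/air parameters, two cameras imaging
every 30 minutes between 06:00 and 18:00, sensor records every 5 minutes,
and a humidifier plus grow/ring lights as actuators.

Configuration is a plain YAML mapping layered over these defaults; any subset
of keys may be overridden.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import time
from typing import Optional

import yaml

PARAMETERS = ("pH", "EC", "water_temp", "RH", "air_temp", "light")


@dataclass(frozen=True)
class DiurnalProfile:
    """Two-level day/night profile with additive Gaussian noise.

    ``day_level`` applies inside the day window (06:00-18:00 by default),
    ``night_level`` outside it. ``noise_sd`` is the per-sample standard
    deviation in the parameter's own units.
    """

    day_level: float
    night_level: float
    noise_sd: float = 0.0
    units: str = ""


@dataclass(frozen=True)
class RHDynamics:
    """First-order relative-humidity response to the humidifier.

    RH relaxes exponentially toward ``ceiling`` while the humidifier is on
    (time constant ``tau_rise_min``) and toward the ambient two-level profile
    while it is off (``tau_decay_min``). Ambient night level sits ~18% above
    the day level, mirroring the observed higher night-time humidity.
    """

    ambient_day: float = 45.0
    ambient_night: float = 53.0
    ceiling: float = 90.0
    tau_rise_min: float = 20.0
    tau_decay_min: float = 45.0
    noise_sd: float = 0.0
    initial: float = 60.0
    initial_humidifier_on: bool = True


@dataclass(frozen=True)
class PlantSpec:
    """Per-plant growth trajectory parameters.

    Daily rates are percent area growth per day for each camera view; the
    defaults are the three observed plants' side/top rates.
    """

    initial_side_area: float = 2.0   # cm^2 at day 0
    initial_top_area: float = 2.5    # cm^2 at day 0
    side_rate: float = 15.0          # %/day
    top_rate: float = 15.0           # %/day
    growth_noise_sd: float = 0.0     # multiplicative lognormal sd per epoch


@dataclass(frozen=True)
class CameraConfig:
    scale_cm_per_px: float = 0.05
    image_shape: tuple[int, int] = (192, 512)  # rows, cols
    side_aspect: float = 0.8   # height / width of the side silhouette
    top_aspect: float = 1.0    # depth / width of the top silhouette


@dataclass(frozen=True)
class ControlConfig:
    rh_off_threshold: float = 80.0   # humidifier turn-off limit (%)
    rh_on_threshold: float = 50.0    # humidifier turn-on limit (%)
    lux_on_threshold: float = 450.0  # grow light on below this (lux)
    lux_off_threshold: float = 600.0 # grow light off at/above this (lux)
    photoperiod_start: time = time(6, 0)
    photoperiod_end: time = time(18, 0)
    band_fraction: float = 0.15


@dataclass(frozen=True)
class StageConfig:
    n_stages: int = 12
    reference_final_area: float = 12.0  # cm^2, averaged day-14 area


@dataclass(frozen=True)
class SimConfig:
    """Full simulation configuration; defaults are the reference conditions."""

    duration_days: int = 14
    start_date: str = "2022-06-01"
    seed: int = 0
    record_interval_min: int = 5
    imaging_interval_min: int = 30
    day_start: time = time(6, 0)
    day_end: time = time(18, 0)
    profiles: dict[str, DiurnalProfile] = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    rh: RHDynamics = field(default_factory=RHDynamics)
    plants: tuple[PlantSpec, ...] = field(default_factory=lambda: DEFAULT_PLANTS)
    camera: CameraConfig = field(default_factory=CameraConfig)
    control: ControlConfig = field(default_factory=ControlConfig)
    stages: StageConfig = field(default_factory=StageConfig)

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        for name, prof in self.profiles.items():
            if prof.noise_sd < 0:
                raise ValueError(f"noise_sd for {name} must be >= 0")
        for spec in self.plants:
            if spec.side_rate <= -100 or spec.top_rate <= -100:
                raise ValueError("growth rates must exceed -100%")


# Day/night levels follow the reported diurnal means: pH 6.9 day / 7.05 night,
# EC 2500 day / 2550 night. Water/air temperature and light noise magnitudes
# are placeholders for unreported sensor noise (zero here; override to add).
DEFAULT_PROFILES: dict[str, DiurnalProfile] = {
    "pH": DiurnalProfile(6.9, 7.05, 0.0, "pH"),
    "EC": DiurnalProfile(2500.0, 2550.0, 0.0, "µS/cm"),
    "water_temp": DiurnalProfile(25.0, 24.5, 0.0, "°C"),
    "air_temp": DiurnalProfile(27.0, 23.5, 0.0, "°C"),
    "light": DiurnalProfile(700.0, 0.0, 0.0, "lux"),
}

# The three observed plants' per-view daily growth rates.
DEFAULT_PLANTS: tuple[PlantSpec, ...] = (
    PlantSpec(side_rate=14.7, top_rate=15.6),
    PlantSpec(side_rate=10.25, top_rate=18.67),
    PlantSpec(side_rate=22.73, top_rate=23.16),
)


def _parse_time(value) -> time:
    if isinstance(value, time):
        return value
    h, m = str(value).split(":")
    return time(int(h), int(m))


def _profiles_from_dict(d: dict) -> dict[str, DiurnalProfile]:
    out = dict(DEFAULT_PROFILES)
    for name, spec in d.items():
        base = out.get(name, DiurnalProfile(0.0, 0.0))
        out[name] = dataclasses.replace(base, **spec)
    return out


def config_from_dict(raw: dict) -> SimConfig:
    """Build a SimConfig from a nested mapping layered over the defaults."""
    raw = dict(raw or {})
    kwargs: dict = {}
    sim = raw.get("simulation", {})
    for key in ("duration_days", "start_date", "seed",
                "record_interval_min", "imaging_interval_min"):
        if key in sim:
            kwargs[key] = sim[key]
    if "day_start" in sim:
        kwargs["day_start"] = _parse_time(sim["day_start"])
    if "day_end" in sim:
        kwargs["day_end"] = _parse_time(sim["day_end"])
    if "sensors" in raw:
        kwargs["profiles"] = _profiles_from_dict(raw["sensors"])
    if "rh_dynamics" in raw:
        kwargs["rh"] = RHDynamics(**raw["rh_dynamics"])
    if "plants" in raw:
        kwargs["plants"] = tuple(PlantSpec(**p) for p in raw["plants"])
    if "camera" in raw:
        cam = dict(raw["camera"])
        if "image_shape" in cam:
            cam["image_shape"] = tuple(cam["image_shape"])
        kwargs["camera"] = CameraConfig(**cam)
    if "control" in raw:
        ctl = dict(raw["control"])
        for key in ("photoperiod_start", "photoperiod_end"):
            if key in ctl:
                ctl[key] = _parse_time(ctl[key])
        kwargs["control"] = ControlConfig(**ctl)
    if "stages" in raw:
        kwargs["stages"] = StageConfig(**raw["stages"])
    return SimConfig(**kwargs)


def load_config(path: Optional[str] = None) -> SimConfig:
    """Load a YAML config file merged over the defaults; None gives defaults."""
    if path is None:
        return SimConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def _json_default(obj):
    if isinstance(obj, time):
        return obj.isoformat()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(type(obj).__name__)


def config_digest(config: SimConfig) -> str:
    """Stable SHA-256 digest of the full configuration."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True,
                         default=_json_default)
    return hashlib.sha256(payload.encode()).hexdigest()
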