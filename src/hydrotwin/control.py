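"""Virtual-to-physical feedback: hysteresis actuator control and event log.

The humidifier runs under two-threshold (bang-bang) control: it is switched
off when relative humidity reaches the 80% upper limit and back on when RH
falls to the 50% lower limit; no action is taken inside the dead band, which
prevents chattering. The grow light follows a photoperiod (06:00-18:00) and
a light-intensity threshold: on when measured lux drops below 450 inside the
photoperiod, off at a configured satisfaction level or outside the
photoperiod. Threshold comparisons are inclusive ("reaches" the limit).

Every state change is appended to a structured event log — the software
stand-in for operator e-mail notification. Manual overrides pin an actuator
until explicitly released; automatic control then resumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, time
from typing import Iterable, Optional

from .config import ControlConfig
from .monitor import (DEFAULT_RANGES, ParameterRange, SensorReading,
                      StatusReport, status_reports)

ACTUATORS = ("humidifier", "grow_light", "ring_light")


@dataclass(frozen=True)
class ActuatorState:
    humidifier: bool = False
    grow_light: bool = False
    ring_light: bool = False

    def with_actuator(self, actuator: str, on: bool) -> "ActuatorState":
        if actuator not in ACTUATORS:
            raise ValueError(f"unknown actuator {actuator!r}")
        return replace(self, **{actuator: on})

    def get(self, actuator: str) -> bool:
        if actuator not in ACTUATORS:
            raise ValueError(f"unknown actuator {actuator!r}")
        return getattr(self, actuator)


@dataclass(frozen=True)
class ControlEvent:
    timestamp: datetime
    actuator: str
    command: str              # turn_on | turn_off | release
    trigger: str              # auto | manual
    reason: str = ""

    def as_line(self) -> str:
        return "\t".join([self.timestamp.isoformat(), self.actuator,
                          self.command, self.trigger, self.reason])


def humidifier_step(humidifier_on: bool, rh: float,
                    off_threshold: float = 80.0,
                    on_threshold: float = 50.0) -> str:
    """Hysteresis decision for the humidifier given current RH (%).

    Returns "turn_off" when on and RH >= the upper limit, "turn_on" when off
    and RH <= the lower limit, else "hold".
    """
    if humidifier_on and rh >= off_threshold:
        return "turn_off"
    if not humidifier_on and rh <= on_threshold:
        return "turn_on"
    return "hold"


def light_step(light_on: bool, lux: float, clock_time: time,
               on_threshold: float = 450.0, off_threshold: float = 600.0,
               photoperiod_start: time = time(6, 0),
               photoperiod_end: time = time(18, 0)) -> str:
    """Grow-light decision: photoperiod gate plus lux hysteresis.

    Outside the photoperiod the light is always commanded off. Inside it,
    the light turns on when lux < on_threshold and off once lux reaches
    off_threshold (a dead band avoids flicker when the measured level
    hovers around one threshold).
    """
    if lux < 0:
        raise ValueError("lux must be >= 0")
    in_period = photoperiod_start <= clock_time < photoperiod_end
    if not in_period:
        return "turn_off" if light_on else "hold"
    if not light_on and lux < on_threshold:
        return "turn_on"
    if light_on and lux >= off_threshold:
        return "turn_off"
    return "hold"


_COMMAND_STATE = {"turn_on": True, "turn_off": False}


def plan_cycle(readings: Iterable[SensorReading], state: ActuatorState,
               now: datetime, config: ControlConfig = ControlConfig(),
               ranges: dict[str, ParameterRange] = DEFAULT_RANGES,
               skip: frozenset[str] = frozenset()
               ) -> tuple[list[tuple[str, str, str]], list[StatusReport]]:
    """Pure per-cycle decision: (actuator, command, reason) plans + reports.

    Deterministic in (readings, state, now); performs no state mutation.
    Actuators in ``skip`` (manually pinned) are not planned for.
    """
    readings = list(readings)
    reports = status_reports(readings, ranges, config.band_fraction)
    latest = {r.parameter: r for r in readings}
    plans: list[tuple[str, str, str]] = []
    if "RH" in latest and "humidifier" not in skip:
        rh = latest["RH"].value
        cmd = humidifier_step(state.humidifier, rh,
                              config.rh_off_threshold, config.rh_on_threshold)
        if cmd != "hold":
            limit = (config.rh_off_threshold if cmd == "turn_off"
                     else config.rh_on_threshold)
            plans.append(("humidifier", cmd,
                          f"RH={rh:.2f}% vs limit {limit:.0f}%"))
    if "light" in latest and "grow_light" not in skip:
        lux = latest["light"].value
        cmd = light_step(state.grow_light, lux, now.time(),
                         config.lux_on_threshold, config.lux_off_threshold,
                         config.photoperiod_start, config.photoperiod_end)
        if cmd != "hold":
            plans.append(("grow_light", cmd,
                          f"lux={lux:.0f} at {now.time().isoformat('minutes')}"))
    return plans, reports


class Controller:
    """Stateful feedback controller over the grow bed's actuators.

    Wraps the pure per-cycle planner (:func:`plan_cycle`) with actuator
    state, the append-only event log, and manual-override pinning.
    """

    def __init__(self, config: ControlConfig = ControlConfig(),
                 ranges: dict[str, ParameterRange] = DEFAULT_RANGES,
                 state: ActuatorState = ActuatorState(humidifier=True)):
        self.config = config
        self.ranges = ranges
        self.state = state
        self.events: list[ControlEvent] = []
        self._manual_pins: set[str] = set()

    def manual_override(self, actuator: str, command: str,
                        timestamp: datetime) -> ControlEvent:
        """Pin an actuator to a commanded state until released.

        ``command`` is "turn_on", "turn_off" or "release". The event is
        always logged, even when the commanded state equals the current one.
        """
        if command == "release":
            self._manual_pins.discard(actuator)
            ev = ControlEvent(timestamp, actuator, "release", "manual",
                              "manual override released; auto control resumes")
        elif command in _COMMAND_STATE:
            self.state = self.state.with_actuator(actuator, _COMMAND_STATE[command])
            self._manual_pins.add(actuator)
            ev = ControlEvent(timestamp, actuator, command, "manual",
                              "manual override")
        else:
            raise ValueError(f"unknown command {command!r}")
        self.events.append(ev)
        return ev

    def process_cycle(self, readings: Iterable[SensorReading],
                      now: datetime) -> tuple[list[str], list[ControlEvent],
                                              list[StatusReport]]:
        """One control cycle: classify parameters, decide, apply, log.

        Returns the commands applied this cycle (excluding holds), the
        events logged, and the per-parameter status reports. Manually
        pinned actuators are left untouched by the automatic rules.
        """
        plans, reports = plan_cycle(readings, self.state, now, self.config,
                                    self.ranges, frozenset(self._manual_pins))
        commands, events = [], []
        for actuator, cmd, reason in plans:
            self.state = self.state.with_actuator(actuator, _COMMAND_STATE[cmd])
            ev = ControlEvent(now, actuator, cmd, "auto", reason)
            self.events.append(ev)
            events.append(ev)
            commands.append(cmd)
        return commands, events, reports


def write_event_log(events: Iterable[ControlEvent], path) -> None:
    """Write events as newline-delimited tab-separated records."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(ev.as_line() + "\n")


def read_event_log(path) -> list[ControlEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            ts, actuator, command, trigger, reason = line.rstrip("\n").split("\t")
            events.append(ControlEvent(datetime.fromisoformat(ts), actuator,
                                       command, trigger, reason))
    return events
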