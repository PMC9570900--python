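"""Simulated clock driving the twin's synchronization ("twinning") rates.

Three cadences matter: a 1-second display refresh, a 5-minute sensor-record
interval, and a 30-minute imaging/prediction interval. The clock advances in
fixed integer-second ticks so that every scheduled cadence fires exactly
once per due tick.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterator

TICK_DISPLAY_S = 1
TICK_RECORD_S = 5 * 60
TICK_PREDICT_S = 30 * 60


@dataclass
class TwinClock:
    """Monotone simulated clock ticking at a fixed resolution.

    Iterating yields (elapsed_seconds, datetime) pairs for every tick after
    ``start`` up to and including ``end``; elapsed time is exact integer
    arithmetic, so interval-due checks (elapsed % interval == 0) are robust.
    """

    start: datetime
    end: datetime
    tick_seconds: int = TICK_DISPLAY_S

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must not precede start")
        if self.tick_seconds <= 0:
            raise ValueError("tick_seconds must be positive")

    def __iter__(self) -> Iterator[tuple[int, datetime]]:
        total = int((self.end - self.start).total_seconds())
        for elapsed in range(self.tick_seconds, total + 1, self.tick_seconds):
            yield elapsed, self.start + timedelta(seconds=elapsed)

    def due(self, elapsed: int, interval_seconds: int) -> bool:
        """Whether a cadence with the given interval fires at this tick."""
        return elapsed % interval_seconds == 0
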