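"""Strictly monotonic timestamp source.

Mutating operations must *strictly* advance ``updated_on``; wall-clock reads
can tie within a microsecond, so ties are broken by stepping one microsecond
past the last issued stamp. Tests may swap in a :class:`LogicalClock` for
fully deterministic timestamps.
"""

from __future__ import annotations

import datetime as _dt
import threading

UTC = _dt.timezone.utc


class Clock:
    """Wall clock that never returns the same instant twice."""

    def __init__(self) -> None:
        self._last = _dt.datetime.min.replace(tzinfo=UTC)
        self._mutex = threading.Lock()

    def now(self) -> _dt.datetime:
        with self._mutex:
            t = _dt.datetime.now(tz=UTC)
            if t <= self._last:
                t = self._last + _dt.timedelta(microseconds=1)
            self._last = t
            return t


class LogicalClock(Clock):
    """Deterministic clock: a fixed epoch advanced one second per call."""

    def __init__(self, epoch: _dt.datetime | None = None) -> None:
        super().__init__()
        self._t = epoch or _dt.datetime(2024, 1, 1, tzinfo=UTC)

    def now(self) -> _dt.datetime:
        with self._mutex:
            self._t += _dt.timedelta(seconds=1)
            return self._t


_default = Clock()


def now() -> _dt.datetime:
    """Timestamp from the process-wide default clock."""
    return _default.now()


def set_default_clock(clock: Clock) -> Clock:
    """Replace the process-wide clock (tests inject a LogicalClock); returns the previous one."""
    global _default
    previous = _default
    _default = clock
    return previous
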