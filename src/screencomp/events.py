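"""Poll-based input abstraction.

Device input arrives as :class:`InputEvent` values pulled from an
:class:`EventSource` by an :class:`EventListener`.  The listener
repeatedly polls, offers each event to a chain of handler functions,
and returns the first non-``None`` handler result — or the
:data:`TIMEOUT` sentinel once an optional timeout elapses.  Both the
event source and the clock are injected, so every timing path can be
exercised deterministically with :class:`ScriptedEventSource` and
:class:`SimulatedClock`; a windowed adapter plugs in real devices.

Within one ``listen`` call each polled event is offered to handlers at
most once: first to the listener's permanent handlers (given at
construction), then to the call-site handlers, in order.  Events no
handler consumes are dropped.  A ``quit`` event raises
:class:`UserAbort` after the permanent handlers have seen it.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Protocol, Sequence

from .composition import LayoutTrace, MouseArea
from .geometry import Rect

__all__ = [
    "InputEvent",
    "Keys",
    "TIMEOUT",
    "UserAbort",
    "Clock",
    "SimulatedClock",
    "RealClock",
    "EventSource",
    "ScriptedEventSource",
    "EventListener",
    "mouse_dispatch_handler",
]

Handler = Callable[["InputEvent"], object]


class _TimeoutSentinel:
    """Distinguished 'nothing happened' value; never a valid key or char."""

    _instance: Optional["_TimeoutSentinel"] = None

    def __new__(cls) -> "_TimeoutSentinel":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "TIMEOUT"

    def __bool__(self) -> bool:
        return False


TIMEOUT = _TimeoutSentinel()


class UserAbort(Exception):
    """Raised when the subject or operator closes the session (quit event)."""


class Keys:
    """Abstract key identifiers (plain strings, backend-mapped)."""

    RETURN = "return"
    SPACE = "space"
    ESCAPE = "escape"
    LEFT = "left"
    RIGHT = "right"
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class InputEvent:
    """A single device event.

    Exactly the fields of its ``kind`` are meaningful: ``key`` for
    ``key_down``, ``char`` for ``unicode_char``, ``pos``/``button`` for
    the mouse kinds.  ``time`` is seconds on the listener's clock.
    """

    kind: str
    time: float = 0.0
    key: Optional[str] = None
    char: Optional[str] = None
    pos: Optional[tuple[int, int]] = None
    button: int = 0

    KINDS = ("key_down", "unicode_char", "mouse_down", "mouse_up", "mouse_move", "quit")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")

    @classmethod
    def key_down(cls, key: str, time: float = 0.0) -> "InputEvent":
        return cls("key_down", time=time, key=key)

    @classmethod
    def unicode_char(cls, char: str, time: float = 0.0) -> "InputEvent":
        return cls("unicode_char", time=time, char=char)

    @classmethod
    def mouse_down(
        cls, pos: tuple[int, int], button: int = 1, time: float = 0.0
    ) -> "InputEvent":
        return cls("mouse_down", time=time, pos=pos, button=button)

    @classmethod
    def quit(cls, time: float = 0.0) -> "InputEvent":
        return cls("quit", time=time)


class Clock(Protocol):
    def now(self) -> float: ...

    def sleep(self, dt: float) -> None: ...


class SimulatedClock:
    """Deterministic clock; ``sleep`` advances time, nothing else does.

    Time is held in integer microseconds so that many small sleeps do
    not accumulate floating-point drift — reaction times computed from
    this clock are exact.
    """

    def __init__(self, start: float = 0.0):
        self._us = round(start * 1_000_000)

    def now(self) -> float:
        return self._us / 1_000_000

    def sleep(self, dt: float) -> None:
        if dt < 0:
            raise ValueError(f"cannot sleep a negative duration: {dt}")
        self._us += round(dt * 1_000_000)


class RealClock:
    """Monotonic wall clock for live sessions."""

    def __init__(self) -> None:
        self._epoch = _time.monotonic()

    def now(self) -> float:
        return _time.monotonic() - self._epoch

    def sleep(self, dt: float) -> None:
        if dt > 0:
            _time.sleep(dt)


class EventSource(Protocol):
    def poll(self) -> list[InputEvent]:
        """Pending events in arrival order; each returned at most once."""
        ...


@dataclass
class ScriptedEventSource:
    """Replays a timed event script against an injected clock.

    ``poll()`` releases every scheduled event whose timestamp is
    ``<= clock.now()`` that has not been released yet.
    """

    schedule: list[InputEvent]
    clock: Clock
    _cursor: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        self.schedule = sorted(self.schedule, key=lambda e: e.time)

    def poll(self) -> list[InputEvent]:
        now = self.clock.now()
        batch = []
        while self._cursor < len(self.schedule) and self.schedule[self._cursor].time <= now:
            batch.append(self.schedule[self._cursor])
            self._cursor += 1
        return batch

    @classmethod
    def from_jsonl(cls, lines: Iterable[str], clock: Clock) -> "ScriptedEventSource":
        """Parse JSON-lines event records: ``{"t": 0.5, "kind": "key_down", ...}``."""
        events = []
        for line in lines:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            kind = rec["kind"]
            events.append(
                InputEvent(
                    kind,
                    time=float(rec.get("t", 0.0)),
                    key=rec.get("key"),
                    char=rec.get("char"),
                    pos=tuple(rec["pos"]) if "pos" in rec else None,
                    button=int(rec.get("button", 0)),
                )
            )
        return cls(events, clock)


class EmptyEventSource:
    """A source that never produces events."""

    def poll(self) -> list[InputEvent]:
        return []


def _resolve_timeout(timeout: Optional[float]) -> Optional[float]:
    # absent or <= 0 means wait indefinitely
    if timeout is None or timeout <= 0:
        return None
    return timeout


class EventListener:
    """Polls an event source and routes events through handler chains."""

    def __init__(
        self,
        source: EventSource,
        clock: Optional[Clock] = None,
        permanent_handlers: Sequence[Handler] = (),
        poll_interval: float = 0.001,
    ):
        if poll_interval <= 0:
            raise ValueError(f"poll_interval must be > 0, got {poll_interval}")
        self.source = source
        self.clock: Clock = clock if clock is not None else RealClock()
        self.permanent_handlers = list(permanent_handlers)
        self.poll_interval = poll_interval

    def _offer(self, event: InputEvent, handlers: Sequence[Handler]) -> object:
        for h in self.permanent_handlers:
            result = h(event)
            if result is not None:
                return result
        if event.kind == "quit":
            raise UserAbort("quit event received")
        for h in handlers:
            result = h(event)
            if result is not None:
                return result
        return None

    def listen(
        self, handlers: Sequence[Handler] = (), timeout: Optional[float] = None
    ) -> object:
        """Poll until a handler consumes an event or the timeout elapses.

        Each event is offered to the permanent handlers, then to
        ``handlers``, in order; the first non-``None`` result is
        returned immediately.  With a timeout and no result,
        :data:`TIMEOUT` is returned once the deadline passes.
        """
        handlers = list(handlers)
        if not handlers and not self.permanent_handlers:
            raise ValueError("listen() needs at least one handler")
        deadline = _resolve_timeout(timeout)
        start = self.clock.now()
        while True:
            for event in self.source.poll():
                result = self._offer(event, handlers)
                if result is not None:
                    return result
            if deadline is not None and self.clock.now() - start >= deadline:
                return TIMEOUT
            self.clock.sleep(self.poll_interval)

    def wait_for_keys(
        self, keys: Iterable[str], timeout: Optional[float] = None
    ) -> object:
        """Return the first pressed member of ``keys`` (or :data:`TIMEOUT`)."""
        key_set = set(keys)
        if not key_set:
            raise ValueError("wait_for_keys needs a non-empty key set")

        def handler(event: InputEvent) -> Optional[str]:
            if event.kind == "key_down" and event.key in key_set:
                return event.key
            return None

        return self.listen([handler], timeout=timeout)

    def wait_for_unicode_char(
        self, ignored: Iterable[str] = (), timeout: Optional[float] = None
    ) -> object:
        """Return the first typed unicode char not in ``ignored``."""
        ignored_set = set(ignored)

        def handler(event: InputEvent) -> Optional[str]:
            if event.kind == "unicode_char" and event.char not in ignored_set:
                return event.char
            return None

        return self.listen([handler], timeout=timeout)

    def wait_for_seconds(self, duration: float) -> None:
        """Idle for ``duration`` on the injected clock.

        Events arriving meanwhile are still offered to the permanent
        handlers (results discarded); quit still aborts.
        """
        if duration < 0:
            raise ValueError(f"duration must be >= 0, got {duration}")
        deadline = self.clock.now() + duration
        while self.clock.now() < deadline:
            for event in self.source.poll():
                self._offer(event, ())
            remaining = deadline - self.clock.now()
            if remaining <= 0:
                break
            # never sleep below clock resolution, or a simulated clock
            # could fail to advance on float rounding dust
            self.clock.sleep(min(self.poll_interval, max(remaining, 1e-6)))


def mouse_dispatch_handler(
    areas: LayoutTrace | Sequence[tuple[MouseArea, Rect]],
) -> Handler:
    """Build a handler dispatching mouse events to composed mouse areas.

    ``areas`` is a :class:`~screencomp.composition.LayoutTrace` (its
    registered mouse areas are used) or an explicit ``(area, rect)``
    sequence in compose order.  For a mouse event whose position lies
    inside a rect (half-open containment), the topmost — last-composed —
    matching area's callback is invoked with ``(event, rect)``.  The
    handler always returns ``None`` so dispatch never terminates a
    ``listen`` call by itself.
    """
    pairs = list(areas.mouse_areas if isinstance(areas, LayoutTrace) else areas)

    def handler(event: InputEvent) -> None:
        if event.kind not in ("mouse_down", "mouse_up", "mouse_move") or event.pos is None:
            return None
        px, py = event.pos
        for area, rect in reversed(pairs):
            if rect.contains_point(px, py):
                area.callback(event, rect)
                break
        return None

    return handler
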