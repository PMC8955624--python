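"""Per-event window construction on the streaming sensor data.

The dynamic segmenter builds, for every newly recorded event, a backward
window of spatio-temporally correlated context events.  Starting from the
two most recent events, earlier candidates are admitted one by one while
they pass two gates against the fitted :class:`~stigsense.correlation.CorrelationModel`:

* **SCC** (sensor correlation check): the candidate's SCM value with the
  target sensor reaches the target's SCT;
* **TCC** (time correlation check): the gap between the candidate and the
  current window head stays within the MTI of that ordered sensor pair, and
  the total span up to the target stays within the MTS of the target
  sensor's functional area.

Scanning stops at the first failing candidate, at the stream start, or at a
configurable lookback cap.  Fixed-size event windows and fixed time windows
are provided as the conventional baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

from .correlation import CorrelationModel
from .events import EventStream, SensorEvent


@dataclass
class Window:
    """A contiguous event run whose last event is the classification target."""

    events: list[SensorEvent]
    first_index: int
    target_index: int

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("window must be nonempty")
        if len(self.events) != self.target_index - self.first_index + 1:
            raise ValueError("window events do not match the index range")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def target(self) -> SensorEvent:
        return self.events[-1]

    @property
    def end_time(self) -> float:
        """Window end time Te = time of the last (target) event."""
        return self.events[-1].time_abs

    @property
    def span(self) -> float:
        return self.events[-1].time_abs - self.events[0].time_abs


def scc(model: CorrelationModel, candidate_sensor: int, target_sensor: int) -> bool:
    """Sensor correlation check: SCM(j, i) >= SCT(i); a sensor always
    correlates with itself."""
    s = model.n_sensors
    for idx in (candidate_sensor, target_sensor):
        if not 1 <= idx <= s:
            raise ValueError(f"sensor index {idx} outside 1..{s}")
    if candidate_sensor == target_sensor:
        return True
    return model.scm_value(candidate_sensor, target_sensor) >= model.sct_value(target_sensor)


def tcc(
    model: CorrelationModel,
    candidate: SensorEvent,
    head: SensorEvent,
    target: SensorEvent,
) -> bool:
    """Time correlation check for a candidate preceding the window head.

    True iff the candidate-to-head gap is within MTI(candidate sensor, head
    sensor) and the candidate-to-target span is within MTS of the target
    sensor's area (both boundary cases inclusive).
    """
    gap = head.time_abs - candidate.time_abs
    span = target.time_abs - candidate.time_abs
    if gap > model.mti_value(candidate.sensor, head.sensor):
        return False
    return span <= model.mts_value(model.area_of(target.sensor))


def dynamic_segment(
    stream: EventStream,
    i: int,
    model: CorrelationModel,
    *,
    max_lookback: int = 200,
) -> Window:
    """Dynamic spatio-temporal window ending at event ``i``.

    The window is initialized to the two latest events {E_{i-1}, E_i} (the
    immediately preceding event is admitted unconditionally; the very first
    stream event yields the singleton window).  Candidates are then scanned
    backward and prepended while they pass SCC and TCC; the first failure
    stops the scan.  ``max_lookback`` caps the window length so degenerate
    thresholds cannot make the per-event cost unbounded.
    """
    if not 0 <= i < len(stream):
        raise IndexError(f"target index {i} outside the stream")
    if i == 0:
        return Window([stream.events[0]], 0, 0)
    target = stream.events[i]
    first = i - 1
    for j in range(i - 2, -1, -1):
        if i - j + 1 > max_lookback:
            break
        candidate = stream.events[j]
        if not scc(model, candidate.sensor, target.sensor):
            break
        if not tcc(model, candidate, stream.events[first], target):
            break
        first = j
    return Window(list(stream.events[first : i + 1]), first, i)


def fixed_segment(stream: EventStream, i: int, ws: int) -> Window:
    """Fixed-size event window: the last min(ws, i+1) events ending at ``i``."""
    if ws < 1:
        raise ValueError("ws must be >= 1")
    if not 0 <= i < len(stream):
        raise IndexError(f"target index {i} outside the stream")
    first = max(0, i - ws + 1)
    return Window(list(stream.events[first : i + 1]), first, i)


def time_segment(stream: EventStream, i: int, dt: float) -> Window:
    """Fixed time window: events with time in (T_i - dt, T_i], causally
    restricted to positions <= i."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not 0 <= i < len(stream):
        raise IndexError(f"target index {i} outside the stream")
    cutoff = stream.events[i].time_abs - dt
    first = i
    while first > 0 and stream.events[first - 1].time_abs > cutoff:
        first -= 1
    return Window(list(stream.events[first : i + 1]), first, i)


def segment(
    stream: EventStream,
    i: int,
    *,
    method: str = "ds",
    model: CorrelationModel | None = None,
    ws: int = 15,
    dt: float = 60.0,
    max_lookback: int = 200,
) -> Window:
    """Dispatch to one of the three windowing methods (ds / fs / tw)."""
    if method == "ds":
        if model is None:
            raise ValueError("dynamic segmentation requires a fitted model")
        return dynamic_segment(stream, i, model, max_lookback=max_lookback)
    if method == "fs":
        return fixed_segment(stream, i, ws)
    if method == "tw":
        return time_segment(stream, i, dt)
    raise ValueError(f"unknown segmentation method {method!r}")
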