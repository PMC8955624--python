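"""Reading, labeling, and writing annotated binary sensor-event streams.

The on-disk format is the CASAS-style log: whitespace-delimited text lines

    2010-11-04 02:36:35 M002 ON
    2010-11-04 05:40:51 M013 ON Meal_Preparation begin

i.e. ``date time sensor value [activity marker]`` where ``value`` is one of
ON/OFF (motion sensors) or OPEN/CLOSE (door sensors) and the optional
annotation marks the first/last event of an activity instance.  Sensors and
activities are digitized to 1-based integer indices through :class:`Catalog`
objects; lines whose value is not binary (e.g. temperature readings) are
skipped with a warning because they carry no motion information.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ON_TOKENS = frozenset({"ON", "OPEN", "1"})
OFF_TOKENS = frozenset({"OFF", "CLOSE", "0"})

#: Catch-all class for events outside any annotated activity instance.
OTHER_ACTIVITY = "Other_Activity"


class ParseError(ValueError):
    """Raised for a malformed log line; message names the line number."""


class Catalog:
    """Bidirectional name <-> 1-based index registry.

    A frozen catalog rejects unseen names; an open one appends them in
    first-seen order (the behaviour wanted when digitizing a new home).
    """

    def __init__(self, names: Iterable[str] = (), frozen: bool = False):
        self._names: list[str] = list(names)
        self._index: dict[str, int] = {n: i + 1 for i, n in enumerate(self._names)}
        if len(self._index) != len(self._names):
            raise ValueError("duplicate names in catalog")
        self.frozen = frozen

    def index(self, name: str) -> int:
        """Index of *name*, appending it if the catalog is open."""
        try:
            return self._index[name]
        except KeyError:
            if self.frozen:
                raise KeyError(f"unknown name {name!r} in frozen catalog") from None
            self._names.append(name)
            self._index[name] = len(self._names)
            return self._index[name]

    def name(self, index: int) -> str:
        return self._names[index - 1]

    def names(self) -> list[str]:
        return list(self._names)

    def copy(self, frozen: bool | None = None) -> "Catalog":
        return Catalog(self._names, self.frozen if frozen is None else frozen)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self._names)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Catalog) and self._names == other._names

    def __repr__(self) -> str:
        return f"Catalog({self._names!r}, frozen={self.frozen})"


@dataclass(frozen=True, slots=True)
class SensorEvent:
    """One timestamped binary sensor firing.

    ``time_abs`` is seconds since midnight of the stream's first day, so it is
    monotone across midnight (a sleeping episode keeps a coherent span);
    ``time_of_day`` keeps the per-day display clock.
    """

    date: dt.date
    time_of_day: float
    time_abs: float
    sensor: int
    value: int
    annotation: tuple[str, str] | None = None  # (activity, "begin"|"end")
    label: int | None = None

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"sensor value must be binary, got {self.value!r}")


@dataclass
class EventStream:
    """An ordered stream of :class:`SensorEvent` plus its catalogs."""

    events: list[SensorEvent]
    sensor_catalog: Catalog
    activity_catalog: Catalog = field(default_factory=Catalog)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[SensorEvent]:
        return iter(self.events)

    def __getitem__(self, i: int) -> SensorEvent:
        return self.events[i]

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_catalog)

    @property
    def n_activities(self) -> int:
        return len(self.activity_catalog)

    def time_array(self) -> np.ndarray:
        return np.array([e.time_abs for e in self.events], dtype=float)

    def sensor_array(self) -> np.ndarray:
        return np.array([e.sensor for e in self.events], dtype=np.int64)

    def label_array(self) -> np.ndarray:
        """Labels as an int array; raises if any event is unlabeled."""
        labels = [e.label for e in self.events]
        if any(l is None for l in labels):
            raise ValueError("stream has unlabeled events; run assign_labels first")
        return np.array(labels, dtype=np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [e.date for e in self.events],
                "time_of_day": [e.time_of_day for e in self.events],
                "time_abs": [e.time_abs for e in self.events],
                "sensor": [e.sensor for e in self.events],
                "value": [e.value for e in self.events],
                "annotation": [e.annotation for e in self.events],
                "label": [e.label for e in self.events],
            }
        )

    def equals(self, other: "EventStream", time_tol: float = 1e-6) -> bool:
        """Field-for-field equality, with a tiny tolerance on clock floats."""
        if len(self) != len(other) or self.sensor_catalog != other.sensor_catalog:
            return False
        if self.activity_catalog != other.activity_catalog:
            return False
        for a, b in zip(self.events, other.events):
            if (a.date, a.sensor, a.value, a.annotation, a.label) != (
                b.date,
                b.sensor,
                b.value,
                b.annotation,
                b.label,
            ):
                return False
            if abs(a.time_of_day - b.time_of_day) > time_tol:
                return False
            if abs(a.time_abs - b.time_abs) > time_tol:
                return False
        return True


def _parse_time_of_day(token: str, lineno: int) -> float:
    try:
        t = dt.time.fromisoformat(token)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: bad time {token!r}: {exc}") from None
    return t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6


def _parse_date(token: str, lineno: int) -> dt.date:
    try:
        return dt.date.fromisoformat(token)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: bad date {token!r}: {exc}") from None


def read_casas(
    path: str | Path,
    catalogs: tuple[Catalog, Catalog] | None = None,
    *,
    on_unsorted: str = "sort",
) -> EventStream:
    """Read and digitize a CASAS-style annotated event log.

    Parameters
    ----------
    path
        Text file of ``date time sensor value [activity marker]`` lines.
    catalogs
        Optional ``(sensor_catalog, activity_catalog)`` pair.  Frozen sensor
        catalogs cause unknown sensors to be skipped with a warning; open
        catalogs grow in first-seen order.
    on_unsorted
        ``"sort"`` stably sorts events whose timestamps go backwards (with a
        warning); ``"raise"`` rejects such files.
    """
    if on_unsorted not in ("sort", "raise"):
        raise ValueError("on_unsorted must be 'sort' or 'raise'")
    if catalogs is None:
        sensor_cat, activity_cat = Catalog(), Catalog()
    else:
        sensor_cat, activity_cat = catalogs
        sensor_cat, activity_cat = sensor_cat.copy(), activity_cat.copy()

    raw: list[tuple[dt.date, float, int, int, tuple[str, str] | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 4:
                raise ParseError(f"line {lineno}: expected at least 4 fields, got {len(tokens)}")
            date = _parse_date(tokens[0], lineno)
            tod = _parse_time_of_day(tokens[1], lineno)
            value_token = tokens[3].upper()
            if value_token in ON_TOKENS:
                value = 1
            elif value_token in OFF_TOKENS:
                value = 0
            else:
                log.warning(
                    "line %d: non-binary value %r for sensor %s; skipping",
                    lineno,
                    tokens[3],
                    tokens[2],
                )
                continue
            try:
                sensor = sensor_cat.index(tokens[2])
            except KeyError:
                log.warning("line %d: unknown sensor %s; skipping", lineno, tokens[2])
                continue
            annotation = None
            if len(tokens) > 4:
                if len(tokens) < 6:
                    raise ParseError(
                        f"line {lineno}: annotation needs activity and begin/end marker"
                    )
                marker = tokens[-1].lower()
                if marker not in ("begin", "end"):
                    raise ParseError(f"line {lineno}: bad annotation marker {tokens[-1]!r}")
                activity = " ".join(tokens[4:-1])
                activity_cat.index(activity)
                annotation = (activity, marker)
            raw.append((date, tod, sensor, value, annotation))

    if not raw:
        return EventStream([], sensor_cat, activity_cat)

    base = raw[0][0]
    events = [
        SensorEvent(
            date=d,
            time_of_day=tod,
            time_abs=(d - base).days * 86400.0 + tod,
            sensor=s,
            value=v,
            annotation=ann,
        )
        for d, tod, s, v, ann in raw
    ]
    times = [e.time_abs for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        if on_unsorted == "raise":
            raise ParseError("timestamps are not monotone non-decreasing")
        log.warning("timestamps not monotone; stably sorting %d events", len(events))
        events.sort(key=lambda e: e.time_abs)
    return EventStream(events, sensor_cat, activity_cat)


def assign_labels(stream: EventStream, *, other_activity: str = OTHER_ACTIVITY) -> EventStream:
    """Label every event with its enclosing activity instance.

    Events between an activity's ``begin`` and ``end`` markers (both marker
    events included) receive that activity's index; everything else becomes
    the catch-all class.  Nested/overlapping spans resolve to the innermost
    (most recently opened) span, with a warning.  An ``end`` marker with no
    open matching ``begin`` is an error.  Idempotent; preserves event count.
    """
    activity_cat = stream.activity_catalog.copy(frozen=False)
    other_idx = activity_cat.index(other_activity)
    open_stack: list[str] = []
    out: list[SensorEvent] = []
    for pos, ev in enumerate(stream.events):
        if ev.annotation is not None and ev.annotation[1] == "begin":
            if open_stack:
                log.warning(
                    "event %d: %r begins inside open span(s) %s; innermost wins",
                    pos,
                    ev.annotation[0],
                    open_stack,
                )
            open_stack.append(ev.annotation[0])
        current = open_stack[-1] if open_stack else None
        if ev.annotation is not None and ev.annotation[1] == "end":
            name = ev.annotation[0]
            if name not in open_stack:
                raise ValueError(
                    f"event {pos}: 'end' marker for {name!r} without matching 'begin'"
                )
            # pop the most recent matching begin
            for k in range(len(open_stack) - 1, -1, -1):
                if open_stack[k] == name:
                    del open_stack[k]
                    break
        label = activity_cat.index(current) if current is not None else other_idx
        out.append(replace(ev, label=label))
    if open_stack:
        log.warning("stream ends with unclosed activity span(s): %s", open_stack)
    return EventStream(out, stream.sensor_catalog.copy(), activity_cat)


def _format_time(tod: float) -> str:
    total = round(tod, 6)
    h = int(total // 3600)
    rem = total - 3600 * h
    m = int(rem // 60)
    s = rem - 60 * m
    if abs(s - round(s)) < 5e-7:
        si = int(round(s))
        if si == 60:  # float edge at the minute boundary
            si = 0
            m += 1
            if m == 60:
                m = 0
                h += 1
        return f"{h:02d}:{m:02d}:{si:02d}"
    return f"{h:02d}:{m:02d}:{s:09.6f}".rstrip("0")


def _value_token(stream: EventStream, ev: SensorEvent) -> str:
    name = stream.sensor_catalog.name(ev.sensor)
    if name.startswith("D"):
        return "OPEN" if ev.value else "CLOSE"
    return "ON" if ev.value else "OFF"


def write_casas(stream: EventStream, path: str | Path) -> None:
    """Write a stream back to the CASAS text format (round-trips with
    :func:`read_casas` up to clock microseconds)."""
    with open(path, "w") as fh:
        for ev in stream.events:
            fields = [
                ev.date.isoformat(),
                _format_time(ev.time_of_day),
                stream.sensor_catalog.name(ev.sensor),
                _value_token(stream, ev),
            ]
            if ev.annotation is not None:
                fields.extend(ev.annotation)
            fh.write(" ".join(fields) + "\n")
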