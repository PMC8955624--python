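"""A small hand-built demonstration stream used in the documentation.

Three motion sensors fire over half a minute with the trigger order
M002 -> M001 -> M003 -> M003 -> M002 -> M003, preceded by an earlier M002
activation.  Building the stigmergic network of the marked window therefore
produces the six directed edges (2,2), (2,1), (1,3), (3,3), (3,2), (2,3):
the self-loop (2,2) because the sensor active before the window is again
M002, and the (3,3) self-loop from the repeated M003 trigger.  With
volatilization rate 0.2 the self-loop (2,2) — activation from 27 s to 15 s
before the window end — aggregates to intensity 0.163833, and the final
edge (2,3) — a 2 s activation ending exactly at the window end — to 1.8.
"""

from __future__ import annotations

import datetime as dt

from .events import Catalog, EventStream, SensorEvent
from .segmentation import Window

_DATE = dt.date(2010, 11, 4)

# (seconds since midnight, sensor, value); the window is rows 2..13
_ROWS = [
    (9390, 2, 1),  # 02:36:30 M002 ON   (pre-window history)
    (9393, 2, 0),  # 02:36:33 M002 OFF
    (9395, 2, 1),  # 02:36:35 M002 ON   <- window start
    (9398, 1, 1),  # 02:36:38 M001 ON
    (9401, 3, 1),  # 02:36:41 M003 ON
    (9405, 1, 0),  # 02:36:45 M001 OFF
    (9406, 3, 0),  # 02:36:46 M003 OFF
    (9407, 2, 0),  # 02:36:47 M002 OFF
    (9408, 3, 1),  # 02:36:48 M003 ON
    (9410, 3, 0),  # 02:36:50 M003 OFF
    (9412, 2, 1),  # 02:36:52 M002 ON
    (9415, 2, 0),  # 02:36:55 M002 OFF
    (9420, 3, 1),  # 02:37:00 M003 ON
    (9422, 3, 0),  # 02:37:02 M003 OFF  <- target, Te = 02:37:02
]

_WINDOW_FIRST = 2


def demo_stream() -> EventStream:
    """The 14-event demonstration stream over sensors M001..M003."""
    events = [
        SensorEvent(
            date=_DATE,
            time_of_day=float(t),
            time_abs=float(t),
            sensor=s,
            value=v,
        )
        for t, s, v in _ROWS
    ]
    return EventStream(events, Catalog(["M001", "M002", "M003"]), Catalog())


def demo_window(stream: EventStream | None = None) -> Window:
    """The marked window of :func:`demo_stream` (its last 12 events)."""
    if stream is None:
        stream = demo_stream()
    last = len(stream) - 1
    return Window(list(stream.events[_WINDOW_FIRST:]), _WINDOW_FIRST, last)
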