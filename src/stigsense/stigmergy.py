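"""Stigmergic activity features: directed weighted networks over a window.

Each sensor activation inside a window deposits one unit of "pheromone" per
time step at its position; old deposits evaporate by a volatilization rate
``rho`` per step.  At the window end time Te, the aggregated intensity of an
activation spanning [ts, te) is the geometric sum

    I = sum_{t=ts}^{te-1} (1 - rho)^(Te - t - 1)
      = ((1 - rho)^(Te - te) - (1 - rho)^(Te - ts)) / rho

which degenerates to the plain activation duration te - ts when rho = 0.
The trigger order of the activated sensors strings these intensities onto
the edges of a directed weighted network (DWN): each trigger deposits its
intensity on the edge arriving from the previously triggered sensor, so the
adjacency matrix simultaneously encodes where the resident dwelt (weights)
and the coarse motion trajectory (edge directions).  The activation-duration
feature vector is kept as the conventional order-free baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .events import EventStream
from .segmentation import Window


@dataclass(frozen=True)
class StigmergyParams:
    """Volatilization rate per time step (0 disables decay) and the step
    length in seconds (times are floored to this grid)."""

    rho: float = 0.0
    time_step: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")


@dataclass
class DWN:
    """Directed weighted network of a window, as its adjacency matrix.

    Entry (u, v) is the accumulated pheromone on the edge u -> v; sensors are
    1-based, rows/columns 0-based.
    """

    weights: np.ndarray
    target_label: int | None = None

    def weight(self, u: int, v: int) -> float:
        return float(self.weights[u - 1, v - 1])

    def nonzero_edges(self) -> set[tuple[int, int]]:
        return {(int(u) + 1, int(v) + 1) for u, v in zip(*np.nonzero(self.weights))}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(1, self.weights.shape[0] + 1))
        for u, v in self.nonzero_edges():
            g.add_edge(u, v, weight=self.weight(u, v))
        return g


@dataclass
class FeatureVector:
    """Per-sensor activation durations within a window, plus the target's
    activity label."""

    durations: np.ndarray
    label: int | None = None


def _ticks(t: float, step: float) -> int:
    # small epsilon guards float division like 2.9999999 for 3.0
    return math.floor(t / step + 1e-9)


def pheromone_intensity(
    ts: float, te: float, Te: float, params: StigmergyParams = StigmergyParams()
) -> float:
    """Aggregated pheromone at window end Te of an activation on [ts, te).

    Times are floored to the ``time_step`` grid; the returned intensity is in
    pheromone units (equal to seconds of activation when rho = 0 and
    time_step = 1 s).
    """
    if ts > te:
        raise ValueError(f"activation start {ts} after end {te}")
    if te > Te:
        raise ValueError(f"activation end {te} after window end {Te}")
    n_te = _ticks(Te, params.time_step) - _ticks(te, params.time_step)
    n_ts = _ticks(Te, params.time_step) - _ticks(ts, params.time_step)
    if params.rho == 0.0:
        return float(n_ts - n_te)
    q = 1.0 - params.rho
    return (q**n_te - q**n_ts) / params.rho


def extract_triggers(window: Window, stream: EventStream) -> list[tuple[int, float, float]]:
    """Triggered sensors of a window in time order, as (sensor, ts, te).

    ``ts`` is the ON event's time; ``te`` is the time of the first later OFF
    event of the same sensor at or before the window end Te, else Te (an
    activation still open at the window end is capped there).  Two ON events
    of the same sensor yield two separate triggers.
    """
    te_end = window.end_time
    events = stream.events
    triggers: list[tuple[int, float, float]] = []
    for offset, ev in enumerate(window.events):
        if ev.value != 1:
            continue
        ts = ev.time_abs
        te = te_end
        for p in range(window.first_index + offset + 1, len(events)):
            nxt = events[p]
            if nxt.time_abs > te_end:
                break
            if nxt.sensor == ev.sensor and nxt.value == 0:
                te = nxt.time_abs
                break
        triggers.append((ev.sensor, ts, te))
    return triggers


def _previous_trigger_sensor(window: Window, stream: EventStream, default: int) -> int:
    """Sensor of the last ON event strictly before the window; the first
    trigger itself (a self-loop) when the stream has no earlier activation."""
    for p in range(window.first_index - 1, -1, -1):
        if stream.events[p].value == 1:
            return stream.events[p].sensor
    return default


def build_dwn(
    window: Window,
    stream: EventStream,
    params: StigmergyParams = StigmergyParams(),
) -> DWN:
    """Stigmergic directed weighted network of a window.

    Triggers u_1..u_m (in order) generate the edge chain
    (prev, u_1), (u_1, u_2), ..., (u_{m-1}, u_m) where ``prev`` is the last
    sensor activated before the window; the edge ending at trigger k carries
    that trigger's pheromone intensity, and repeated edges accumulate by
    summation.  A window with no ON events gives the zero matrix.
    """
    s = stream.n_sensors
    weights = np.zeros((s, s))
    triggers = extract_triggers(window, stream)
    label = window.target.label
    if not triggers:
        return DWN(weights, label)
    prev = _previous_trigger_sensor(window, stream, default=triggers[0][0])
    te_end = window.end_time
    for sensor, ts, te in triggers:
        weights[prev - 1, sensor - 1] += pheromone_intensity(ts, te, te_end, params)
        prev = sensor
    return DWN(weights, label)


def build_fv(window: Window, stream: EventStream) -> FeatureVector:
    """Activation-duration feature vector of a window (order-free baseline):
    d_k = total seconds sensor k was active, label = target event's label."""
    durations = np.zeros(stream.n_sensors)
    for sensor, ts, te in extract_triggers(window, stream):
        durations[sensor - 1] += te - ts
    return FeatureVector(durations, window.target.label)
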