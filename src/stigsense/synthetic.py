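"""Seeded generator of annotated smart-home binary sensor streams.

The simulator emulates the statistical structure an ambient-sensing ADL
recognizer relies on: sensors grouped into functional areas, activities that
run as random walks over their area's sensors, ON events on arrival with a
lognormal dwell before the OFF, occasional cross-area "noise" firings,
begin/end annotations on the first/last event of every instance, exponential
idle gaps between instances with a few unannotated wander events, and
irregular inter-event times throughout.  Everything is drawn from one seeded
``numpy`` generator, so a configuration reproduces its stream byte for byte.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np

from .correlation import CorrelationConfig
from .events import OTHER_ACTIVITY, Catalog, EventStream, SensorEvent

_START_DATE = dt.date(2024, 1, 6)
_START_SECONDS = 8 * 3600.0  # 08:00 on day one


@dataclass
class ActivitySpec:
    """One activity class: its home area, normal duration (s), mean
    per-sensor dwell (s), and the preferred direction of its walk.

    ``direction`` (+1 or -1) is the cyclic order in which the activity tends
    to visit its area's sensors — ADLs are directional (entering vs leaving,
    a cooking circuit vs a clean-up circuit), which is what trajectory-aware
    features can exploit.
    """

    name: str
    area: int
    duration_mean: float
    duration_sd: float
    dwell_mean: float
    direction: int = 1


@dataclass
class SimConfig:
    """Study conditions for one simulated home.

    ``areas`` lists the 1-based sensor indices each functional area owns
    (area k = position k in the list); within an area the walk is dense,
    across areas sensors only fire through the ``noise`` probability.
    """

    areas: list[list[int]]
    activities: list[ActivitySpec]
    transition: list[list[float]] | None = None
    gap_mean: float = 90.0
    gap_event_rate: float = 2.0
    noise: float = 0.05
    horizon: int = 100
    seed: int = 0
    dwell_sigma: float = 0.6
    direction_p: float = 0.7  # chance a step follows the activity's cyclic order

    def validate(self) -> None:
        if not self.areas or any(not a for a in self.areas):
            raise ValueError("every area must own at least one sensor")
        flat = [s for area in self.areas for s in area]
        if len(set(flat)) != len(flat):
            raise ValueError("sensor indices must be unique across areas")
        if sorted(flat) != list(range(1, len(flat) + 1)):
            raise ValueError("sensor indices must be contiguous 1..S")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must be in [0, 1)")
        if self.gap_mean <= 0 or self.horizon < 1:
            raise ValueError("gap_mean must be > 0 and horizon >= 1")
        for act in self.activities:
            if not 1 <= act.area <= len(self.areas):
                raise ValueError(f"activity {act.name!r} references unknown area {act.area}")
            if act.duration_mean <= 0 or act.duration_sd < 0 or act.dwell_mean <= 0:
                raise ValueError(f"activity {act.name!r} has non-positive durations")
        if self.transition is not None:
            t = np.asarray(self.transition, dtype=float)
            k = len(self.activities)
            if t.shape != (k, k) or (t < 0).any() or (t.sum(axis=1) <= 0).any():
                raise ValueError("transition must be a nonnegative KxK matrix with positive rows")

    @property
    def n_sensors(self) -> int:
        return sum(len(a) for a in self.areas)

    @property
    def sensor_area(self) -> dict[int, int]:
        return {s: k + 1 for k, area in enumerate(self.areas) for s in area}

    @property
    def activity_area(self) -> dict[str, int]:
        return {a.name: a.area for a in self.activities}


def mini_home(seed: int = 0, *, horizon: int = 100, noise: float = 0.05) -> SimConfig:
    """Default small-home fixture: 3 areas x 3 sensors, 5 activities plus
    the implicit catch-all, sized so integration runs take seconds.

    Activities sharing an area share a duration distribution, so each area's
    configured duration mean + 2·sd is well defined; they differ in their
    per-sensor dwell (a resident cooking moves between stations faster than
    one washing up) and in the preferred direction of their walk, so both
    duration-based and trajectory-aware features have signal to recover.
    """
    return SimConfig(
        areas=[[1, 2, 3], [4, 5, 6], [7, 8, 9]],
        activities=[
            ActivitySpec("Cooking", 1, 120.0, 25.0, 5.0, direction=1),
            ActivitySpec("Dishwashing", 1, 120.0, 25.0, 12.0, direction=-1),
            ActivitySpec("Relaxing", 2, 150.0, 30.0, 12.0, direction=1),
            ActivitySpec("Napping", 2, 150.0, 30.0, 5.0, direction=-1),
            ActivitySpec("Desk_Work", 3, 90.0, 20.0, 8.0, direction=1),
        ],
        gap_mean=90.0,
        gap_event_rate=2.0,
        noise=noise,
        horizon=horizon,
        seed=seed,
    )


def mini_home_correlation_config(config: SimConfig | None = None) -> CorrelationConfig:
    """Offline-phase configuration matching a simulated home's layout."""
    cfg = config if config is not None else mini_home()
    return CorrelationConfig(
        sensor_area=cfg.sensor_area,
        activity_area=cfg.activity_area,
        scm_window=15,
        sct_rank=2,
    )


def _transition_matrix(config: SimConfig) -> np.ndarray:
    k = len(config.activities)
    if config.transition is None:
        return np.full((k, k), 1.0 / k)
    t = np.asarray(config.transition, dtype=float)
    return t / t.sum(axis=1, keepdims=True)


def simulate_stream(config: SimConfig) -> EventStream:
    """Generate an annotated (unlabeled) stream from the configuration.

    Call :func:`stigsense.events.assign_labels` on the result to turn the
    begin/end annotations into per-event labels.
    """
    config.validate()
    # separate substreams: the activity schedule can be replayed on its own
    rng_sched = np.random.default_rng([config.seed, 11])
    rng = np.random.default_rng([config.seed, 7])
    trans = _transition_matrix(config)
    all_sensors = sorted(s for area in config.areas for s in area)

    records: list[list] = []  # [time, sensor, value, annotation]
    t = _START_SECONDS
    act_idx = int(rng_sched.integers(len(config.activities)))
    for _ in range(config.horizon):
        act = config.activities[act_idx]
        area_sensors = config.areas[act.area - 1]
        out_of_area = [s for s in all_sensors if s not in area_sensors]
        duration = max(
            act.duration_mean + act.duration_sd * rng.standard_normal(), act.dwell_mean
        )
        inst: list[list] = []
        t0 = t
        end_t = t0 + duration  # final OFF is clamped here, so the realized
        # instance duration matches the drawn one
        pos = int(rng.integers(len(area_sensors)))  # walk position within the area
        while not inst or t < end_t:
            if out_of_area and rng.random() < config.noise:
                sensor = int(out_of_area[rng.integers(len(out_of_area))])
            else:
                if rng.random() < config.direction_p:
                    pos = (pos + act.direction) % len(area_sensors)
                else:
                    pos = int(rng.integers(len(area_sensors)))
                sensor = int(area_sensors[pos])
            dwell = rng.lognormal(
                math.log(act.dwell_mean) - config.dwell_sigma**2 / 2.0, config.dwell_sigma
            )
            on_t = round(t, 3)
            off_t = round(min(t + max(dwell, 0.05), end_t), 3)
            if off_t <= on_t:
                off_t = on_t + 0.001
            inst.append([on_t, sensor, 1, None])
            inst.append([off_t, sensor, 0, None])
            t = off_t + round(float(rng.uniform(0.2, 1.0)), 3)
            if off_t >= end_t - 1e-9:
                break
        inst[0][3] = (act.name, "begin")
        inst[-1][3] = (act.name, "end")
        records.extend(inst)

        gap = float(rng.exponential(config.gap_mean))
        gap_start = inst[-1][0] + 0.5
        gap_end = inst[-1][0] + max(gap, 2.0)
        n_wander = int(rng.poisson(config.gap_event_rate))
        wander: list[list] = []
        for _ in range(n_wander):
            if gap_end - gap_start < 4.0:
                break
            wt = round(float(rng.uniform(gap_start + 0.5, gap_end - 2.5)), 3)
            sensor = int(all_sensors[rng.integers(len(all_sensors))])
            wd = round(wt + float(rng.uniform(0.5, 2.0)), 3)
            wander.append([wt, sensor, 1, None])
            wander.append([wd, sensor, 0, None])
        wander.sort(key=lambda r: r[0])
        records.extend(wander)
        t = gap_end + 0.5
        act_idx = int(rng_sched.choice(len(config.activities), p=trans[act_idx]))

    records.sort(key=lambda r: r[0])
    events = []
    for time_abs, sensor, value, ann in records:
        days = int(time_abs // 86400)
        events.append(
            SensorEvent(
                date=_START_DATE + dt.timedelta(days=days),
                time_of_day=time_abs - 86400.0 * days,
                time_abs=time_abs,
                sensor=sensor,
                value=value,
                annotation=ann,
            )
        )
    sensor_catalog = Catalog([f"M{i:03d}" for i in range(1, config.n_sensors + 1)])
    activity_catalog = Catalog([a.name for a in config.activities] + [OTHER_ACTIVITY])
    return EventStream(events, sensor_catalog, activity_catalog)


@dataclass
class InstanceSpan:
    """One annotated activity instance: closed event-index range."""

    activity: str
    first_index: int
    last_index: int

    def __contains__(self, idx: int) -> bool:
        return self.first_index <= idx <= self.last_index


def ground_truth_windows(stream: EventStream) -> tuple[list[InstanceSpan], np.ndarray]:
    """Oracle segmentation: each event's enclosing activity instance.

    Returns the instance spans and an array mapping each event index to its
    span's position (-1 for gap events outside every instance — the
    catch-all pseudo-span).
    """
    spans: list[InstanceSpan] = []
    open_spans: dict[str, list[int]] = {}
    for pos, ev in enumerate(stream.events):
        if ev.annotation is None:
            continue
        name, marker = ev.annotation
        if marker == "begin":
            open_spans.setdefault(name, []).append(pos)
        elif open_spans.get(name):
            start = open_spans[name].pop()
            spans.append(InstanceSpan(name, start, pos))
    spans.sort(key=lambda s: s.first_index)
    membership = np.full(len(stream), -1, dtype=np.int64)
    for k, span in enumerate(spans):
        membership[span.first_index : span.last_index + 1] = k
    return spans, membership
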