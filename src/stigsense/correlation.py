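"""Offline phase: spatio-temporal correlation statistics of a labeled stream.

Four quantities are learned from annotated training data and later drive the
dynamic segmentation of the live stream:

* **SCM** — sensor correlation matrix: ``SCM[i, j]`` is the probability that
  sensors *i* and *j* co-occur in a sliding window of ``ws`` consecutive
  events (stride 1).  Presence, not multiplicity, is counted, so it is a
  symmetric matrix with entries in [0, 1]; the diagonal is each sensor's
  window occupancy.
* **SCT** — per-sensor correlation threshold: the minimum SCM value a
  candidate sensor must reach to count as spatially correlated with the
  target.  Either looked up against an explicit per-sensor *key sensor*
  (manual layout knowledge) or taken as the k-th largest off-diagonal entry
  of the sensor's SCM row.
* **MTI** — maximum time interval: for each ordered sensor pair (a, b)
  observed on consecutive events, the mean + 2·std of the inter-event gaps;
  pairs never observed fall back to a global mean + 2·std.
* **MTS** — maximum time span: per clustered functional area, the
  mean + 2·std of the durations of the activity instances mapped there.

Standard deviations are the population form (ddof=0) by default; a single
observation contributes std 0.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import EventStream

log = logging.getLogger(__name__)


@dataclass
class CorrelationConfig:
    """Configuration of the offline phase.

    ``sensor_area`` maps 1-based sensor index -> 1-based functional area;
    ``activity_area`` maps activity name -> area.  Activities absent from
    ``activity_area`` are assigned to the area where the majority of their
    training events fire (with a warning).  Exactly one of ``key_sensors``
    (sensor -> its geographically critical sensor) or ``sct_rank`` selects
    the SCT rule.
    """

    sensor_area: dict[int, int]
    activity_area: dict[str, int] = field(default_factory=dict)
    scm_window: int = 15
    sct_rank: int | None = 2
    key_sensors: dict[int, int] | None = None
    ddof: int = 0

    @property
    def n_areas(self) -> int:
        return max(self.sensor_area.values())


@dataclass
class CorrelationModel:
    """Products of the offline phase, consumed by the segmentation checks."""

    scm: np.ndarray
    sct: np.ndarray
    mti: np.ndarray  # NaN where the ordered pair was never observed
    mti_fallback: float
    mts: np.ndarray
    sensor_area: dict[int, int]
    scm_window: int

    @property
    def n_sensors(self) -> int:
        return self.scm.shape[0]

    @property
    def n_areas(self) -> int:
        return len(self.mts)

    def scm_value(self, i: int, j: int) -> float:
        return float(self.scm[i - 1, j - 1])

    def sct_value(self, i: int) -> float:
        return float(self.sct[i - 1])

    def mti_value(self, a: int, b: int) -> float:
        """Threshold for sensor *a* firing immediately before *b*; unseen
        transitions use the global fallback rather than blocking."""
        v = self.mti[a - 1, b - 1]
        return self.mti_fallback if np.isnan(v) else float(v)

    def mts_value(self, area: int) -> float:
        return float(self.mts[area - 1])

    def area_of(self, sensor: int) -> int:
        return self.sensor_area[sensor]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "scm": self.scm.tolist(),
            "sct": self.sct.tolist(),
            "mti": [[None if np.isnan(v) else v for v in row] for row in self.mti],
            "mti_fallback": self.mti_fallback,
            "mts": self.mts.tolist(),
            "sensor_area": {str(k): v for k, v in self.sensor_area.items()},
            "scm_window": self.scm_window,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CorrelationModel":
        if isinstance(source, Path):
            text = source.read_text()
        elif source.lstrip().startswith("{"):
            text = source
        else:
            text = Path(source).read_text()
        d = json.loads(text)
        mti = np.array(
            [[np.nan if v is None else v for v in row] for row in d["mti"]], dtype=float
        )
        return cls(
            scm=np.array(d["scm"], dtype=float),
            sct=np.array(d["sct"], dtype=float),
            mti=mti,
            mti_fallback=float(d["mti_fallback"]),
            mts=np.array(d["mts"], dtype=float),
            sensor_area={int(k): v for k, v in d["sensor_area"].items()},
            scm_window=int(d["scm_window"]),
        )

    def equals(self, other: "CorrelationModel", tol: float = 0.0) -> bool:
        def close(a, b):
            return np.allclose(a, b, rtol=0.0, atol=tol, equal_nan=True)

        return (
            close(self.scm, other.scm)
            and close(self.sct, other.sct)
            and close(self.mti, other.mti)
            and abs(self.mti_fallback - other.mti_fallback) <= tol
            and close(self.mts, other.mts)
            and self.sensor_area == other.sensor_area
            and self.scm_window == other.scm_window
        )


def compute_scm(stream: EventStream, ws: int) -> np.ndarray:
    """Windowed co-occurrence probability matrix.

    Entry (i, j) is the fraction of the N − ws + 1 sliding windows of ``ws``
    consecutive events (stride 1) that contain both sensor i and sensor j at
    least once.
    """
    if ws < 2:
        raise ValueError(f"ws must be >= 2, got {ws}")
    n = len(stream)
    if n < ws:
        raise ValueError(f"stream has {n} events, fewer than ws={ws}")
    sensors = stream.sensor_array() - 1
    s = stream.n_sensors
    counts = np.zeros((s, s))
    n_windows = n - ws + 1
    for k in range(n_windows):
        u = np.unique(sensors[k : k + ws])
        counts[np.ix_(u, u)] += 1.0
    return counts / n_windows


def derive_sct(
    scm: np.ndarray,
    *,
    key_sensors: dict[int, int] | None = None,
    rank: int | None = None,
) -> np.ndarray:
    """Per-sensor correlation threshold from the SCM.

    In key-sensor mode ``sct[i] = scm[i, key_sensors[i]]`` (the manually
    chosen geographically critical neighbour); in rank mode it is the k-th
    largest off-diagonal value of row i.
    """
    s = scm.shape[0]
    sct = np.zeros(s)
    if key_sensors is not None:
        for i in range(1, s + 1):
            if i not in key_sensors:
                raise KeyError(f"key_sensors has no entry for sensor {i}")
            sct[i - 1] = scm[i - 1, key_sensors[i] - 1]
        return sct
    k = 1 if rank is None else rank
    if k < 1:
        raise ValueError("rank must be >= 1")
    for i in range(s):
        off = np.delete(scm[i], i)
        if off.size == 0:
            continue
        sct[i] = np.sort(off)[::-1][min(k, off.size) - 1]
    return sct


def compute_mti(stream: EventStream, *, ddof: int = 0) -> tuple[np.ndarray, float]:
    """Per ordered sensor pair, mean + 2·std of consecutive-event gaps.

    Returns ``(mti, fallback)`` where unseen pairs are NaN in ``mti`` and
    ``fallback`` is mean + 2·std over all consecutive gaps.
    """
    n = len(stream)
    if n < 2:
        raise ValueError("need at least two events to compute MTI")
    t = stream.time_array()
    s = stream.sensor_array()
    gaps = np.diff(t)
    samples: dict[tuple[int, int], list[float]] = defaultdict(list)
    for p in range(n - 1):
        samples[(int(s[p]), int(s[p + 1]))].append(float(gaps[p]))
    size = stream.n_sensors
    mti = np.full((size, size), np.nan)
    for (a, b), vals in samples.items():
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=ddof)) if arr.size > 1 else 0.0
        mti[a - 1, b - 1] = float(arr.mean()) + 2.0 * sd
    fb_sd = float(gaps.std(ddof=ddof)) if gaps.size > 1 else 0.0
    fallback = float(gaps.mean()) + 2.0 * fb_sd
    return mti, fallback


def activity_instances(stream: EventStream) -> list[tuple[str, int, int, float]]:
    """Matched begin/end spans as ``(activity, first_idx, last_idx, duration)``.

    Pairing is lenient: unmatched markers (e.g. spans cut by a fold boundary)
    are dropped with a warning rather than raising.
    """
    open_spans: dict[str, list[int]] = defaultdict(list)
    out: list[tuple[str, int, int, float]] = []
    for pos, ev in enumerate(stream.events):
        if ev.annotation is None:
            continue
        name, marker = ev.annotation
        if marker == "begin":
            open_spans[name].append(pos)
        else:
            if not open_spans[name]:
                log.warning("event %d: unmatched 'end' for %r dropped", pos, name)
                continue
            start = open_spans[name].pop()
            dur = stream.events[pos].time_abs - stream.events[start].time_abs
            out.append((name, start, pos, dur))
    for name, starts in open_spans.items():
        for start in starts:
            log.warning("event %d: unmatched 'begin' for %r dropped", start, name)
    out.sort(key=lambda rec: rec[1])
    return out


def _majority_area(
    stream: EventStream,
    spans: list[tuple[str, int, int, float]],
    sensor_area: dict[int, int],
) -> int:
    votes: dict[int, int] = defaultdict(int)
    for _, start, end, _ in spans:
        for ev in stream.events[start : end + 1]:
            votes[sensor_area[ev.sensor]] += 1
    return max(sorted(votes), key=votes.get)


def compute_mts(
    stream: EventStream,
    sensor_area: dict[int, int],
    activity_area: dict[str, int],
    *,
    n_areas: int | None = None,
    ddof: int = 0,
) -> np.ndarray:
    """Per functional area, mean + 2·std of activity-instance durations.

    Areas with no mapped instances fall back to the global mean + 2·std of
    all instance durations.  Activities missing from ``activity_area`` are
    assigned to the area where the majority of their training events fire.
    """
    instances = activity_instances(stream)
    if not instances:
        raise ValueError("stream has no matched begin/end activity instances")
    k = n_areas if n_areas is not None else max(sensor_area.values())

    by_name: dict[str, list[tuple[str, int, int, float]]] = defaultdict(list)
    for rec in instances:
        by_name[rec[0]].append(rec)
    resolved: dict[str, int] = {}
    for name, spans in by_name.items():
        if name in activity_area:
            resolved[name] = activity_area[name]
        else:
            resolved[name] = _majority_area(stream, spans, sensor_area)
            log.warning(
                "activity %r has no configured area; majority vote assigns area %d",
                name,
                resolved[name],
            )

    durations_by_area: dict[int, list[float]] = defaultdict(list)
    for name, _, _, dur in instances:
        durations_by_area[resolved[name]].append(dur)

    all_d = np.array([rec[3] for rec in instances])
    fb_sd = float(all_d.std(ddof=ddof)) if all_d.size > 1 else 0.0
    fallback = float(all_d.mean()) + 2.0 * fb_sd
    mts = np.full(k, fallback)
    for area, vals in durations_by_area.items():
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=ddof)) if arr.size > 1 else 0.0
        mts[area - 1] = float(arr.mean()) + 2.0 * sd
    return mts


def fit_correlation_model(stream: EventStream, config: CorrelationConfig) -> CorrelationModel:
    """Run the whole offline phase on an annotated training stream."""
    missing = [s for s in range(1, stream.n_sensors + 1) if s not in config.sensor_area]
    if missing:
        raise ValueError(f"sensor_area is missing sensors {missing}")
    scm = compute_scm(stream, config.scm_window)
    sct = derive_sct(scm, key_sensors=config.key_sensors, rank=config.sct_rank)
    mti, fallback = compute_mti(stream, ddof=config.ddof)
    mts = compute_mts(
        stream,
        config.sensor_area,
        config.activity_area,
        n_areas=config.n_areas,
        ddof=config.ddof,
    )
    return CorrelationModel(
        scm=scm,
        sct=sct,
        mti=mti,
        mti_fallback=fallback,
        mts=mts,
        sensor_area=dict(config.sensor_area),
        scm_window=config.scm_window,
    )
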