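import datetime as dt

import numpy as np
import pytest

from stigsense import (
    Catalog,
    EventStream,
    SensorEvent,
    assign_labels,
    fit_correlation_model,
    simulate_stream,
)
from stigsense.synthetic import mini_home, mini_home_correlation_config


def make_stream(rows, n_sensors=None, activities=()):
    """Build a stream from (time_abs, sensor, value[, annotation]) rows.

    Times are seconds; the date is derived so streams can cross midnight.
    """
    events = []
    for row in rows:
        t, sensor, value = row[:3]
        ann = row[3] if len(row) > 3 else None
        days = int(t // 86400)
        events.append(
            SensorEvent(
                date=dt.date(2024, 1, 6) + dt.timedelta(days=days),
                time_of_day=float(t) - 86400.0 * days,
                time_abs=float(t),
                sensor=int(sensor),
                value=int(value),
                annotation=ann,
            )
        )
    if n_sensors is None:
        n_sensors = max((e.sensor for e in events), default=0)
    return EventStream(
        events,
        Catalog([f"M{i:03d}" for i in range(1, n_sensors + 1)]),
        Catalog(list(activities)),
    )


def random_onoff_stream(rng, n_events, n_sensors, max_gap=10.0):
    """Random binary stream with irregular positive gaps (no annotations)."""
    t = 0.0
    rows = []
    for _ in range(n_events):
        t += float(rng.uniform(0.1, max_gap))
        rows.append((round(t, 3), int(rng.integers(1, n_sensors + 1)), int(rng.integers(2))))
    return make_stream(rows, n_sensors=n_sensors)


@pytest.fixture(scope="session")
def mini_stream():
    """Labeled mini-home stream under the default study conditions."""
    return assign_labels(simulate_stream(mini_home(seed=7)))


@pytest.fixture(scope="session")
def mini_model(mini_stream):
    return fit_correlation_model(mini_stream, mini_home_correlation_config(mini_home(seed=7)))
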