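import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stigsense import (
    CorrelationModel,
    assign_labels,
    compute_mti,
    compute_mts,
    compute_scm,
    derive_sct,
    fit_correlation_model,
    simulate_stream,
)
from stigsense.correlation import activity_instances
from stigsense.synthetic import mini_home, mini_home_correlation_config

from conftest import make_stream, random_onoff_stream


def brute_force_scm(stream, ws):
    """Independent oracle: enumerate every window and test pair membership."""
    sensors = [e.sensor for e in stream.events]
    s = stream.n_sensors
    n_windows = len(sensors) - ws + 1
    out = np.zeros((s, s))
    for i in range(1, s + 1):
        for j in range(1, s + 1):
            hits = 0
            for k in range(n_windows):
                window = sensors[k : k + ws]
                if i in window and j in window:
                    hits += 1
            out[i - 1, j - 1] = hits / n_windows
    return out


class TestScm:
    def test_alternating_pair_always_cooccurs(self):
        rows = [(float(t), 1 + t % 2, 1) for t in range(10)]
        scm = compute_scm(make_stream(rows), ws=2)
        assert scm[0, 1] == 1.0

    def test_distant_sensors_never_cooccur(self):
        rows = [(float(t), 1, 1) for t in range(5)] + [(float(t + 5), 2, 1) for t in range(5)]
        scm = compute_scm(make_stream(rows), ws=2)
        # sensors 1 and 2 share exactly the one boundary window
        assert scm[0, 1] == pytest.approx(1 / 9)
        rows = [(float(t), 1, 1) for t in range(5)] + [(float(t + 5), 3, 1) for t in range(5)]
        scm3 = compute_scm(make_stream(rows, n_sensors=3), ws=2)
        assert scm3[0, 1] == 0.0  # sensor 2 never fires at all

    def test_three_window_enumeration(self):
        # windows of [1,1,2,3,2] at ws=3: {1,1,2},{1,2,3},{2,3,2}
        stream = make_stream([(0.0, 1, 1), (1.0, 1, 1), (2.0, 2, 1), (3.0, 3, 1), (4.0, 2, 1)])
        scm = compute_scm(stream, ws=3)
        assert scm[1, 2] == pytest.approx(2 / 3)
        assert scm[0, 2] == pytest.approx(1 / 3)
        assert scm[0, 1] == pytest.approx(2 / 3)

    def test_matches_brute_force_oracle_on_random_streams(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            stream = random_onoff_stream(rng, n_events=int(rng.integers(30, 200)), n_sensors=6)
            ws = int(rng.integers(2, 12))
            np.testing.assert_allclose(
                compute_scm(stream, ws), brute_force_scm(stream, ws), atol=1e-12
            )

    def test_rejects_short_stream_and_bad_ws(self):
        stream = make_stream([(0.0, 1, 1), (1.0, 2, 1)])
        with pytest.raises(ValueError):
            compute_scm(stream, ws=3)
        with pytest.raises(ValueError):
            compute_scm(stream, ws=1)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        data=st.lists(st.integers(min_value=1, max_value=5), min_size=4, max_size=60),
        ws=st.integers(min_value=2, max_value=6),
    )
    def test_symmetry_and_range_property(self, data, ws):
        if len(data) < ws:
            data = data * ws
        stream = make_stream(
            [(float(t), s, 1) for t, s in enumerate(data)], n_sensors=5
        )
        scm = compute_scm(stream, ws)
        np.testing.assert_allclose(scm, scm.T, atol=0)
        assert scm.min() >= 0.0 and scm.max() <= 1.0


class TestSct:
    def test_key_sensor_lookup(self):
        scm = np.array([[1.0, 0.9, 0.5, 0.1]] * 4)
        sct = derive_sct(scm, key_sensors={1: 3, 2: 1, 3: 1, 4: 1})
        assert sct[0] == 0.5

    def test_rank_one_is_max_off_diagonal(self):
        scm = np.array([[1.0, 0.2, 0.7], [0.2, 1.0, 0.4], [0.7, 0.4, 1.0]])
        np.testing.assert_allclose(derive_sct(scm, rank=1), [0.7, 0.4, 0.7])

    def test_all_zero_row_gives_zero_threshold(self):
        scm = np.zeros((3, 3))
        assert derive_sct(scm, rank=2)[1] == 0.0

    def test_missing_key_sensor_raises(self):
        with pytest.raises(KeyError):
            derive_sct(np.eye(3), key_sensors={1: 2})


class TestMti:
    def test_constant_gaps_have_zero_spread(self):
        rows = [(0.0, 1, 1), (2.0, 2, 1), (4.0, 1, 1), (6.0, 2, 1), (8.0, 1, 1), (10.0, 2, 1)]
        mti, _ = compute_mti(make_stream(rows))
        assert mti[0, 1] == pytest.approx(2.0)

    def test_population_stdev_two_samples(self):
        # gaps 1 and 3 for the ordered pair (1, 2): mean 2, population sigma 1
        rows = [(0.0, 1, 1), (1.0, 2, 1), (5.0, 1, 1), (8.0, 2, 1)]
        mti, _ = compute_mti(make_stream(rows))
        assert mti[0, 1] == pytest.approx(4.0)
        # the sample form (ddof=1) gives mean + 2 * sqrt(2)
        mti_sample, _ = compute_mti(make_stream(rows), ddof=1)
        assert mti_sample[0, 1] == pytest.approx(2.0 + 2.0 * math.sqrt(2.0))

    def test_unobserved_pair_is_nan_with_global_fallback(self):
        rows = [(0.0, 1, 1), (1.0, 2, 1), (2.0, 1, 1)]
        mti, fallback = compute_mti(make_stream(rows))
        assert np.isnan(mti[0, 0])
        assert fallback == pytest.approx(1.0)

    def test_spread_monotonicity(self):
        def mti_for(gaps):
            rows, t = [], 0.0
            for g in gaps:
                rows.append((t, 1, 1))
                rows.append((t + g, 2, 1))
                t += g + 100.0
            return compute_mti(make_stream(rows))[0][0, 1]

        narrow = mti_for([5.0, 5.0, 5.0, 5.0])
        wide = mti_for([2.0, 8.0, 2.0, 8.0])  # same mean, larger sigma
        assert wide > narrow


class TestMts:
    def test_equal_durations(self):
        rows = [
            (0.0, 1, 1, ("A", "begin")),
            (60.0, 1, 0, ("A", "end")),
            (100.0, 1, 1, ("A", "begin")),
            (160.0, 1, 0, ("A", "end")),
        ]
        mts = compute_mts(make_stream(rows), {1: 1}, {"A": 1})
        assert mts[0] == pytest.approx(60.0)

    def test_two_sigma_point(self):
        rows = [
            (0.0, 1, 1, ("A", "begin")),
            (30.0, 1, 0, ("A", "end")),
            (100.0, 1, 1, ("A", "begin")),
            (190.0, 1, 0, ("A", "end")),
        ]
        mts = compute_mts(make_stream(rows), {1: 1}, {"A": 1})
        assert mts[0] == pytest.approx(120.0)  # mean 60 + 2 * sigma 30

    def test_unmapped_activity_uses_majority_event_area(self, caplog):
        rows = [
            (0.0, 2, 1, ("Mystery", "begin")),
            (10.0, 2, 0, None),
            (20.0, 1, 1, None),
            (30.0, 2, 1, ("Mystery", "end")),
        ]
        stream = make_stream(rows)
        with caplog.at_level(logging.WARNING):
            mts = compute_mts(stream, {1: 1, 2: 2}, {}, n_areas=2)
        assert "majority" in caplog.text
        assert mts[1] == pytest.approx(30.0)

    def test_area_without_instances_gets_global_fallback(self):
        rows = [
            (0.0, 1, 1, ("A", "begin")),
            (50.0, 1, 0, ("A", "end")),
        ]
        mts = compute_mts(make_stream(rows), {1: 1}, {"A": 1}, n_areas=3)
        assert mts[1] == mts[2] == pytest.approx(50.0)

    def test_no_instances_raises(self):
        with pytest.raises(ValueError):
            compute_mts(make_stream([(0.0, 1, 1)]), {1: 1}, {})

    def test_instances_are_paired_leniently(self, caplog):
        rows = [
            (0.0, 1, 1, ("A", "end")),  # orphan end: dropped
            (10.0, 1, 1, ("A", "begin")),
            (30.0, 1, 0, ("A", "end")),
            (40.0, 1, 1, ("A", "begin")),  # dangling begin: dropped
        ]
        with caplog.at_level(logging.WARNING):
            instances = activity_instances(make_stream(rows))
        assert [(n, i, j) for n, i, j, _ in instances] == [("A", 1, 2)]
        assert "unmatched" in caplog.text


class TestFitModel:
    def test_fit_is_deterministic(self):
        stream = assign_labels(simulate_stream(mini_home(seed=5, horizon=15)))
        cfg = mini_home_correlation_config(mini_home(seed=5))
        assert fit_correlation_model(stream, cfg).equals(fit_correlation_model(stream, cfg))

    def test_serialization_round_trip(self, mini_model, tmp_path):
        path = tmp_path / "model.json"
        mini_model.to_json(path)
        assert CorrelationModel.from_json(path).equals(mini_model)

    def test_thresholds_strictly_positive(self, mini_model):
        valid = mini_model.mti[~np.isnan(mini_model.mti)]
        assert (valid > 0).all()
        assert (mini_model.mts > 0).all()
        assert mini_model.mti_fallback > 0

    def test_within_area_correlation_exceeds_cross_area(self, mini_model):
        area = mini_model.sensor_area
        s = mini_model.n_sensors
        within, cross = [], []
        for i in range(1, s + 1):
            for j in range(i + 1, s + 1):
                (within if area[i] == area[j] else cross).append(mini_model.scm[i - 1, j - 1])
        assert np.mean(within) > np.mean(cross)
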