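"""Per-event classification over DWN / feature-vector features.

Any object with ``fit(X, y)`` and ``predict(X)`` can serve as the classifier
(a deep sequence model plugs in behind the same contract); the shipped
reference is a multinomial logistic regression chosen so the full pipeline
trains in seconds on one CPU.  Training rows are canonically sorted before
fitting, making the fit invariant to sample order, and the solver is seeded,
so end-to-end runs are deterministic.

``cross_validate`` drives the whole pipeline with contiguous temporal folds:
for each fold the correlation model (SCM/SCT/MTI/MTS) is fitted on the
training blocks only, every event's window is segmented causally on the
stream, featurized, and the held-out block is scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .correlation import CorrelationConfig, fit_correlation_model
from .evaluation import MetricsReport, confusion_matrix, weighted_metrics
from .events import EventStream
from .segmentation import segment
from .stigmergy import StigmergyParams, build_dwn, build_fv

log = logging.getLogger(__name__)


@dataclass
class LabeledFeatureSet:
    """Flattened feature matrix (one row per target event) with labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_kind: str
    target_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels differ in length")

    def __len__(self) -> int:
        return len(self.labels)


class ReferenceClassifier:
    """Seeded multinomial logistic regression with order-invariant fitting.

    A single-class training set degenerates to a constant predictor with a
    warning rather than failing.
    """

    def __init__(self, *, C: float = 1.0, max_iter: int = 1000, seed: int = 0):
        self.C = C
        self.max_iter = max_iter
        self.seed = seed
        self._pipeline = None
        self._constant: int | None = None
        self._n_features: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ReferenceClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if len(X) == 0:
            raise ValueError("empty training set")
        self._n_features = X.shape[1]
        if len(np.unique(y)) == 1:
            log.warning("single-class training set; using a constant predictor")
            self._constant = int(y[0])
            self._pipeline = None
            return self
        # canonical row order -> fit independent of sample permutation
        order = np.lexsort(np.vstack([X.T, y[None, :]]))
        self._constant = None
        self._pipeline = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=self.C, max_iter=self.max_iter, random_state=self.seed),
        )
        self._pipeline.fit(X[order], y[order])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._n_features is None:
            raise ValueError("classifier is not fitted")
        if X.shape[1] != self._n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match fitted {self._n_features}"
            )
        if self._constant is not None:
            return np.full(len(X), self._constant, dtype=np.int64)
        return self._pipeline.predict(X).astype(np.int64)


def fit(train: LabeledFeatureSet, hyperparams: dict | None = None, seed: int = 0):
    """Fit the reference classifier on a labeled feature set."""
    clf = ReferenceClassifier(seed=seed, **(hyperparams or {}))
    return clf.fit(train.features, train.labels)


def predict(model, features: np.ndarray) -> np.ndarray:
    return model.predict(features)


def build_feature_set(
    stream: EventStream,
    *,
    method: str = "ds",
    feature: str = "dwn",
    model=None,
    params: StigmergyParams = StigmergyParams(),
    ws: int = 15,
    dt: float = 60.0,
    max_lookback: int = 200,
    stride: int = 1,
    targets=None,
) -> LabeledFeatureSet:
    """Segment and featurize target events of a labeled stream.

    ``targets`` restricts the target positions (default: every ``stride``-th
    event).  DWN matrices are flattened row-major.
    """
    if feature not in ("dwn", "fv"):
        raise ValueError(f"unknown feature kind {feature!r}")
    if targets is None:
        targets = range(0, len(stream), stride)
    rows, labels, indices = [], [], []
    for i in targets:
        win = segment(
            stream, i, method=method, model=model, ws=ws, dt=dt, max_lookback=max_lookback
        )
        if feature == "dwn":
            rows.append(build_dwn(win, stream, params).weights.ravel())
        else:
            rows.append(build_fv(win, stream).durations)
        label = stream.events[i].label
        if label is None:
            raise ValueError(f"event {i} is unlabeled; run assign_labels first")
        labels.append(label)
        indices.append(i)
    return LabeledFeatureSet(
        features=np.array(rows),
        labels=np.array(labels, dtype=np.int64),
        feature_kind=feature,
        target_indices=np.array(indices, dtype=np.int64),
    )


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    fold_bounds: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "folds": [r.to_dict() for r in self.fold_reports],
            "pooled": self.pooled.to_dict(),
            "fold_bounds": self.fold_bounds,
        }


def cross_validate(
    stream: EventStream,
    corr_config: CorrelationConfig,
    *,
    method: str = "ds",
    feature: str = "dwn",
    params: StigmergyParams = StigmergyParams(),
    ws: int = 15,
    dt: float = 60.0,
    max_lookback: int = 200,
    folds: int = 5,
    stride: int = 1,
    seed: int = 0,
    classifier_factory=None,
) -> CrossValidationResult:
    """Contiguous-block k-fold evaluation of the full pipeline.

    The stream is cut into ``folds`` contiguous time blocks.  Per fold, the
    offline phase (SCM/SCT/MTI/MTS) runs on the training blocks only — test
    events never enter threshold fitting — then every event's window is
    built causally on the stream, featurized, and the classifier trained on
    training-block targets predicts the held-out block.
    """
    n = len(stream)
    if n < folds:
        raise ValueError(f"stream of {n} events cannot be split into {folds} folds")
    labels = stream.label_array()
    n_classes = stream.n_activities
    blocks = np.array_split(np.arange(n), folds)
    if classifier_factory is None:
        classifier_factory = lambda fold_seed: ReferenceClassifier(seed=fold_seed)

    reports: list[MetricsReport] = []
    bounds: list[tuple[int, int]] = []
    pooled_cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    for f, test_idx in enumerate(blocks):
        lo, hi = int(test_idx[0]), int(test_idx[-1])
        bounds.append((lo, hi))
        train_events = stream.events[:lo] + stream.events[hi + 1 :]
        assert len(train_events) + len(test_idx) == n  # leakage guard
        train_stream = EventStream(
            train_events, stream.sensor_catalog, stream.activity_catalog
        )
        corr_model = fit_correlation_model(train_stream, corr_config) if method == "ds" else None

        train_targets = [i for i in range(0, n, stride) if not lo <= i <= hi]
        test_targets = [i for i in range(0, n, stride) if lo <= i <= hi]
        common = dict(
            method=method,
            feature=feature,
            model=corr_model,
            params=params,
            ws=ws,
            dt=dt,
            max_lookback=max_lookback,
        )
        train_fs = build_feature_set(stream, targets=train_targets, **common)
        test_fs = build_feature_set(stream, targets=test_targets, **common)

        fold_seed = (seed * 1000 + f) % (2**31 - 1)
        clf = classifier_factory(fold_seed)
        clf.fit(train_fs.features, train_fs.labels)
        pred = clf.predict(test_fs.features)
        cm = confusion_matrix(test_fs.labels, pred, n_classes)
        pooled_cm += cm
        reports.append(weighted_metrics(cm))
    return CrossValidationResult(reports, weighted_metrics(pooled_cm), bounds)
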