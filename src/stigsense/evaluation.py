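"""Confusion matrix and support-weighted multiclass metrics.

Per-event predictions over A activity classes are tallied into an A x A
confusion matrix (rows = true class, columns = predicted).  One-vs-rest
precision P_j = TP_j / (TP_j + FP_j) and recall R_j = TP_j / (TP_j + FN_j)
are averaged with the true-class supports N_j as weights; accuracy is the
trace over the total and the weighted F1 is the harmonic mean of the
weighted precision and recall.  Classes never predicted (or never present)
get precision/recall 0 with a warning so the weighted means stay defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    support: np.ndarray
    accuracy: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float

    @property
    def n_classes(self) -> int:
        return self.confusion.shape[0]

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "support": self.support.tolist(),
            "accuracy": self.accuracy,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
        }

    def summary(self) -> str:
        lines = [
            f"{'class':>6} {'precision':>10} {'recall':>10} {'support':>10}",
        ]
        for j in range(self.n_classes):
            lines.append(
                f"{j + 1:>6} {self.precision[j]:>10.4f} {self.recall[j]:>10.4f}"
                f" {int(self.support[j]):>10}"
            )
        lines.append("")
        lines.append(f"accuracy          {self.accuracy:.4f}")
        lines.append(f"weighted precision {self.precision_weighted:.4f}")
        lines.append(f"weighted recall    {self.recall_weighted:.4f}")
        lines.append(f"weighted F1        {self.f1_weighted:.4f}")
        return "\n".join(lines)


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix with entry (a, b) = events of true class a predicted b
    (classes are 1-based)."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"label sequences differ in length: {t.shape} vs {p.shape}")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} labels outside 1..{n_classes}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t - 1, p - 1), 1)
    return cm


def weighted_metrics(confusion: np.ndarray) -> MetricsReport:
    """Support-weighted precision/recall/F1 and accuracy from a confusion
    matrix.  Supports N_j are the true-class row sums."""
    cm = np.asarray(confusion, dtype=np.int64)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)
    predicted = cm.sum(axis=0).astype(float)

    precision = np.zeros_like(tp)
    recall = np.zeros_like(tp)
    for j in range(cm.shape[0]):
        if predicted[j] > 0:
            precision[j] = tp[j] / predicted[j]
        else:
            log.warning("class %d never predicted; precision set to 0", j + 1)
        if support[j] > 0:
            recall[j] = tp[j] / support[j]
        else:
            log.warning("class %d has no true samples; recall set to 0", j + 1)

    w = support / support.sum()
    p_bar = float(np.dot(w, precision))
    r_bar = float(np.dot(w, recall))
    acc = float(tp.sum() / total)
    f1 = 2.0 * p_bar * r_bar / (p_bar + r_bar) if (p_bar + r_bar) > 0 else 0.0
    return MetricsReport(
        confusion=cm,
        precision=precision,
        recall=recall,
        support=support,
        accuracy=acc,
        precision_weighted=p_bar,
        recall_weighted=r_bar,
        f1_weighted=f1,
    )


def evaluate_labels(y_true, y_pred, n_classes: int) -> MetricsReport:
    """Convenience wrapper: confusion matrix + weighted metrics in one call."""
    return weighted_metrics(confusion_matrix(y_true, y_pred, n_classes))
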