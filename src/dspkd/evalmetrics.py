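"""Confusion-matrix metrics for multi-class skin-lesion classification.

Per-class precision, recall, specificity and F1 are derived one-vs-rest
from a K x K confusion matrix (rows = actual class, columns = predicted);
overall accuracy is the matrix trace over the total, and the macro-average
F1 is the unweighted mean of the per-class F1 scores — the summary used to
rank distillation methods under class imbalance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix",
           "per_class_metrics", "macro_f1", "evaluate_predictions"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints, rows actual / columns predicted
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")
        if not self.labels:
            self.labels = [str(i) for i in range(self.counts.shape[0])]

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) of class ``k`` by marginalization."""
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum() - tp)
        fn = int(self.counts[k, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass
class MetricsReport:
    labels: list[str]
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_f1: float
    degenerate: np.ndarray  # True where a 0/0 metric was reported as 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": self.labels,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
        })

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class": self.to_frame().to_dict(orient="records"),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion_matrix(y_true, y_pred, n_classes: int,
                     labels: list[str] | None = None) -> ConfusionMatrix:
    """Tally a K x K confusion matrix from integer label arrays."""
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.size == 0:
        raise ValueError("empty label arrays")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, labels or [])


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest precision/recall/specificity/F1 per class, plus overall
    accuracy (trace / total) and macro-F1.

    Metrics with a zero denominator are reported as 0 and flagged in
    ``degenerate`` — this only occurs for classes absent from both truth
    and prediction.
    """
    k = cm.n_classes
    precision = np.zeros(k)
    recall = np.zeros(k)
    specificity = np.zeros(k)
    f1 = np.zeros(k)
    degenerate = np.zeros(k, dtype=bool)
    for i in range(k):
        tp, fp, fn, tn = cm.one_vs_rest(i)
        precision[i], d1 = _safe_div(tp, tp + fp)
        recall[i], d2 = _safe_div(tp, tp + fn)
        specificity[i], d3 = _safe_div(tn, tn + fp)
        f1[i], d4 = _safe_div(2 * precision[i] * recall[i], precision[i] + recall[i])
        degenerate[i] = d1 or d2 or d3 or d4
    accuracy = float(np.trace(cm.counts)) / cm.total
    report = MetricsReport(cm.labels, precision, recall, specificity, f1,
                           accuracy, float(f1.mean()), degenerate)
    return report


def macro_f1(report: MetricsReport) -> float:
    """Unweighted mean of the per-class F1 scores."""
    return float(np.mean(report.f1))


def evaluate_predictions(y_true, y_pred, n_classes: int,
                         labels: list[str] | None = None) -> MetricsReport:
    """Convenience wrapper: labels -> confusion matrix -> full report."""
    return per_class_metrics(confusion_matrix(y_true, y_pred, n_classes, labels))
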