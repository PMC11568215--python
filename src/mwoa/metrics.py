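"""Multiclass evaluation: confusion matrix, mean per-class error, and
one-vs-rest accuracy / precision / recall.

Mean per-class error (MCE) is the average over classes of each class's
misclassification rate — equivalently ``1 - macro recall``.  It is the
quantity the feature-selection wrapper minimises, and it is robust to
class imbalance in a way plain accuracy is not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "mean_per_class_error",
    "accuracy_precision_recall",
    "sample_std",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes 1..K, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(c < 0):
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def to_csv(self) -> str:
        K = self.n_classes
        header = "true\\pred," + ",".join(str(k) for k in range(1, K + 1))
        rows = [
            f"{t + 1}," + ",".join(str(int(v)) for v in self.counts[t]) for t in range(K)
        ]
        return "\n".join([header, *rows]) + "\n"


@dataclass(frozen=True)
class MetricsReport:
    mce: float
    accuracy: float
    macro_precision: float
    macro_recall: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "mce": self.mce,
                "accuracy": self.accuracy,
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "per_class_precision": self.per_class_precision.tolist(),
                "per_class_recall": self.per_class_recall.tolist(),
            },
            indent=2,
        )


def confusion(true_labels, predicted_labels, n_classes: int) -> ConfusionMatrix:
    """Count matrix with ``counts[t-1, p-1] = #(true == t, predicted == p)``.

    Labels must lie in ``{1..n_classes}``; any stray label is rejected
    with the index of the first offending row.
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted label sequences differ in length")
    for name, arr in (("true", t), ("predicted", p)):
        bad = (arr < 1) | (arr > n_classes)
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise ValueError(
                f"{name} label {arr[idx]} at row {idx} outside 1..{n_classes}"
            )
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t - 1, p - 1), 1)
    return ConfusionMatrix(counts)


def mean_per_class_error(cm: ConfusionMatrix, strict: bool = False) -> float:
    """Average over classes of ``1 - recall_k``.

    Classes with no true samples are excluded from the mean (or rejected
    when ``strict``).
    """
    counts = cm.counts
    row_totals = counts.sum(axis=1)
    present = row_totals > 0
    if not np.all(present):
        if strict:
            missing = np.flatnonzero(~present) + 1
            raise ValueError(f"classes with no true samples: {missing.tolist()}")
    if not np.any(present):
        raise ValueError("confusion matrix is empty")
    recalls = np.diag(counts)[present] / row_totals[present]
    return float(np.mean(1.0 - recalls))


def accuracy_precision_recall(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest per-class precision/recall, macro averages, and the
    overall multiclass accuracy ``trace(cm) / n``.

    A class never predicted gets precision 0 (the 0/0 case).
    """
    counts = cm.counts.astype(float)
    n = counts.sum()
    if n == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    present = counts.sum(axis=1) > 0
    return MetricsReport(
        mce=mean_per_class_error(cm),
        accuracy=float(tp.sum() / n),
        macro_precision=float(np.mean(precision)),
        macro_recall=float(np.mean(recall[present])),
        per_class_precision=precision,
        per_class_recall=recall,
    )


def sample_std(values) -> float:
    """Sample standard deviation with the n-1 denominator."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("sample_std requires at least two values")
    return float(np.std(v, ddof=1))
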