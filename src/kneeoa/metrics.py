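"""Confusion matrix and micro/macro classification metrics.

Micro metrics pool the one-vs-rest TP/TN/FP/FN counts across classes before
forming each ratio; macro metrics average the per-class ratios unweighted.
In both forms F1 is the harmonic mean of the reported precision and recall.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ConfusionMatrix", "confusion_matrix", "micro_metrics", "macro_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C count matrix; rows are actual labels, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(counts < 0):
            raise ValueError("confusion matrix entries must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self) -> dict[str, np.ndarray]:
        """Per-class TP, FP, FN, TN vectors."""
        cm = self.counts
        tp = np.diag(cm).astype(np.int64)
        fp = cm.sum(axis=0) - tp
        fn = cm.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")


def confusion_matrix(actual, predicted, num_classes: int) -> ConfusionMatrix:
    actual = np.asarray(actual, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    if actual.size and (
        actual.min() < 0 or actual.max() >= num_classes
        or predicted.min() < 0 or predicted.max() >= num_classes
    ):
        raise ValueError(f"labels must lie in [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (actual, predicted), 1)
    return ConfusionMatrix(counts)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {name}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def micro_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Pooled one-vs-rest metrics (the summed-count form)."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics for an empty confusion matrix")
    ovr = cm.one_vs_rest()
    tp, fp, fn, tn = (int(ovr[k].sum()) for k in ("tp", "fp", "fn", "tn"))
    accuracy = _safe_ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": _f1(precision, recall),
    }


def macro_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Unweighted average of per-class one-vs-rest metrics."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics for an empty confusion matrix")
    if cm.num_classes < 2:
        raise ValueError("macro metrics need at least two classes")
    ovr = cm.one_vs_rest()
    tp, fp, fn, tn = ovr["tp"], ovr["fp"], ovr["fn"], ovr["tn"]
    per_acc, per_prec, per_rec = [], [], []
    for c in range(cm.num_classes):
        per_acc.append(
            _safe_ratio(int(tp[c] + tn[c]), cm.total, f"accuracy[class {c}]")
        )
        per_prec.append(_safe_ratio(int(tp[c]), int(tp[c] + fp[c]), f"precision[class {c}]"))
        per_rec.append(_safe_ratio(int(tp[c]), int(tp[c] + fn[c]), f"recall[class {c}]"))
    precision = float(np.mean(per_prec))
    recall = float(np.mean(per_rec))
    return {
        "accuracy": float(np.mean(per_acc)),
        "precision": precision,
        "recall": recall,
        "f1": _f1(precision, recall),
    }


def metrics_report(
    cm: ConfusionMatrix, task: str, split: str
) -> list[dict]:
    """Both averaging forms as JSON-ready rows."""
    rows = []
    for averaging, fn in (("micro", micro_metrics), ("macro", macro_metrics)):
        row = {"task": task, "split": split, "averaging": averaging}
        row.update(fn(cm))
        rows.append(row)
    return rows


def write_metrics(rows: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(rows, indent=2))
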