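"""Confusion-matrix construction and metrics for frame-level subphase labels.

Counts are stored as integers (rows = true class, columns = predicted) over
the 14 subphase classes in cyclic order; normalised views are computed on
demand. Zero-support classes receive precision = recall = F1 = 0 (they are
neither dropped nor NaN), so the macro-F1 always averages over all 14
classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .segmentation import SUBPHASE_LABELS


class LabelValidationError(ValueError):
    """Label sequences disagree in length or contain unknown labels."""


class EmptyMatrixError(ValueError):
    """Metrics were requested for a matrix with no counted frames."""


@dataclass
class ConfusionMatrix14:
    """Integer count table over an ordered class set (default: 14 subphases)."""

    counts: np.ndarray
    labels: Tuple[str, ...] = SUBPHASE_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, key: Tuple[str, str]) -> int:
        true, pred = key
        return int(self.counts[self.labels.index(true), self.labels.index(pred)])

    def normalized(self) -> np.ndarray:
        """Row-stochastic view (per-true-class rates) for display."""
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / row
        return np.nan_to_num(out)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix14":
        df = pd.read_csv(path, index_col=0)
        return cls(counts=df.to_numpy(dtype=np.int64),
                   labels=tuple(df.columns))


def build_confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
                    labels: Tuple[str, ...] = SUBPHASE_LABELS) -> ConfusionMatrix14:
    """Tally ``counts[i, j]`` = frames with true class i predicted as j."""
    if len(true_labels) != len(predicted_labels):
        raise LabelValidationError(
            f"length mismatch: {len(true_labels)} true vs "
            f"{len(predicted_labels)} predicted"
        )
    known = set(labels)
    for pos, (t, p) in enumerate(zip(true_labels, predicted_labels)):
        if t not in known:
            raise LabelValidationError(f"unknown true label {t!r} at position {pos}")
        if p not in known:
            raise LabelValidationError(f"unknown predicted label {p!r} at position {pos}")
    counts = _sk_confusion_matrix(list(true_labels), list(predicted_labels),
                                  labels=list(labels))
    return ConfusionMatrix14(counts=counts.astype(np.int64), labels=tuple(labels))


@dataclass
class ClassificationReport:
    """Per-class precision/recall/F1 plus accuracy and macro-F1."""

    labels: Tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_f1: float
    support: np.ndarray

    def as_dict(self) -> Dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class": {
                label: {"precision": float(p), "recall": float(r),
                        "f1": float(f), "support": int(s)}
                for label, p, r, f, s in zip(
                    self.labels, self.precision, self.recall, self.f1, self.support)
            },
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True))

    def to_text(self) -> str:
        width = max(len(label) for label in self.labels)
        lines = [f"{'class':<{width}}  precision  recall      f1  support"]
        for label, p, r, f, s in zip(self.labels, self.precision, self.recall,
                                     self.f1, self.support):
            lines.append(f"{label:<{width}}  {p:9.3f}  {r:6.3f}  {f:6.3f}  {int(s):7d}")
        lines.append(f"accuracy {self.accuracy:.3f}  macro-F1 {self.macro_f1:.3f}")
        return "\n".join(lines)


def classification_report(cm: ConfusionMatrix14) -> ClassificationReport:
    """Metrics from a confusion matrix.

    precision_k = diag_k / colsum_k, recall_k = diag_k / rowsum_k,
    F1_k their harmonic mean; zero-sum rows/columns yield 0 (not NaN).
    Accuracy = trace / total; macro-F1 = unweighted mean over all classes.
    """
    if cm.total == 0:
        raise EmptyMatrixError("confusion matrix has no counted frames")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    colsum = counts.sum(axis=0)
    rowsum = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(colsum > 0, diag / colsum, 0.0)
        recall = np.where(rowsum > 0, diag / rowsum, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1),
                      0.0)
    return ClassificationReport(
        labels=cm.labels, precision=precision, recall=recall, f1=f1,
        accuracy=float(diag.sum() / counts.sum()), macro_f1=float(f1.mean()),
        support=rowsum.astype(np.int64),
    )
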