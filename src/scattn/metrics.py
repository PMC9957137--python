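"""Evaluation metrics: accuracy, macro precision/recall/F1, multi-class MCC.

Accuracy, macro-averaged precision/recall/F1 and the confusion matrix are
delegated to scikit-learn. The Matthews correlation coefficient is computed
directly from the confusion matrix in its multi-class (covariance / R_K)
form, which reduces exactly to the familiar binary
(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) expression when there
are two classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn import metrics as skm


def _check_lengths(true_labels, predicted_labels):
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("true and predicted label vectors must match in length")
    if true_labels.size == 0:
        raise ValueError("cannot score an empty label vector")
    return true_labels, predicted_labels


def confusion_matrix(true_labels, predicted_labels, label_set) -> np.ndarray:
    """L x L matrix; entry (i, j) counts true label i predicted as j."""
    t, p = _check_lengths(true_labels, predicted_labels)
    return skm.confusion_matrix(t, p, labels=list(label_set))


def accuracy(true_labels, predicted_labels) -> float:
    """Fraction of correct predictions."""
    t, p = _check_lengths(true_labels, predicted_labels)
    return float(skm.accuracy_score(t, p))


def macro_prf(true_labels, predicted_labels, label_set) -> tuple[float, float, float]:
    """Macro-averaged one-vs-rest precision, recall and F1.

    Classes with a zero denominator contribute 0 to the average.
    """
    t, p = _check_lengths(true_labels, predicted_labels)
    prec, rec, f1, _ = skm.precision_recall_fscore_support(
        t, p, labels=list(label_set), average="macro", zero_division=0
    )
    return float(prec), float(rec), float(f1)


def mcc(true_labels, predicted_labels, label_set) -> float:
    """Multi-class Matthews correlation coefficient from the confusion matrix.

    With counts C, per-class true totals t = C.1, predicted totals
    p = C^T.1, n samples and s = trace(C):

        MCC = (s*n - t.p) / sqrt((n^2 - p.p)(n^2 - t.t))

    Degenerate denominators (all-one-class truth or prediction) yield 0.
    """
    C = confusion_matrix(true_labels, predicted_labels, label_set).astype(float)
    t = C.sum(axis=1)
    p = C.sum(axis=0)
    n = C.sum()
    s = np.trace(C)
    cov = s * n - t @ p
    denom = np.sqrt(n * n - p @ p) * np.sqrt(n * n - t @ t)
    if denom == 0:
        return 0.0
    return float(cov / denom)


@dataclass(frozen=True)
class MetricsReport:
    """The five evaluation metrics plus the confusion matrix."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    mcc: float
    confusion: np.ndarray
    label_set: tuple
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "mcc": self.mcc,
            "confusion": self.confusion.tolist(),
            "label_set": [str(x) for x in self.label_set],
            "n": self.n,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def evaluate(true_labels, predicted_labels, label_set=None) -> MetricsReport:
    """Compute all five metrics at once."""
    t, p = _check_lengths(true_labels, predicted_labels)
    if label_set is None:
        label_set = np.unique(np.concatenate([t, p]))
    label_set = tuple(label_set)
    prec, rec, f1 = macro_prf(t, p, label_set)
    return MetricsReport(
        accuracy=accuracy(t, p),
        macro_precision=prec,
        macro_recall=rec,
        macro_f1=f1,
        mcc=mcc(t, p, label_set),
        confusion=confusion_matrix(t, p, label_set),
        label_set=label_set,
        n=t.size,
    )
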