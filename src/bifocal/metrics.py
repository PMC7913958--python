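"""Evaluation metrics: per-class one-vs-rest ROC/AUC, row-normalized
confusion matrices, and macro-averaged precision/sensitivity.

AUC follows the rank (Mann-Whitney) convention — ties between a positive
and a negative score count one half — which is what
:func:`sklearn.metrics.roc_auc_score` computes.  A class that cannot be
evaluated (no positives, or never predicted) is reported as missing and
excluded from the macro average with a warning rather than silently scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvalReport",
    "roc_auc_ovr",
    "confusion_matrix_normalized",
    "precision_sensitivity",
]


@dataclass
class EvalReport:
    per_class_auc: dict[str, float | None]
    macro_auc: float
    confusion: np.ndarray
    precision: float
    sensitivity: float
    auc_mean: float | None = None  # across folds, when cross-validated
    auc_sd: float | None = None
    history: dict | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "per_class_auc": self.per_class_auc,
            "macro_auc": self.macro_auc,
            "confusion": np.asarray(self.confusion).tolist(),
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def roc_auc_ovr(
    labels: np.ndarray, scores: np.ndarray, class_names: list[str] | None = None
) -> tuple[dict[str, float | None], float]:
    """One-vs-rest AUC per class and their unweighted (macro) mean.

    ``labels`` are integer class indices; ``scores`` is (N, C) with one
    score column per class.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if scores.ndim != 2 or len(labels) != len(scores):
        raise ValueError("scores must be (N, C) aligned with labels")
    n_classes = scores.shape[1]
    names = class_names if class_names is not None else [str(c) for c in range(n_classes)]
    aucs: dict[str, float | None] = {}
    valid: list[float] = []
    for c in range(n_classes):
        binary = (labels == c).astype(int)
        if binary.min() == binary.max():
            warnings.warn(
                f"class {names[c]!r} has no positives or no negatives; AUC undefined",
                stacklevel=2,
            )
            aucs[names[c]] = None
            continue
        a = float(roc_auc_score(binary, scores[:, c]))
        aucs[names[c]] = a
        valid.append(a)
    macro = float(np.mean(valid)) if valid else float("nan")
    return aucs, macro


def confusion_matrix_normalized(
    labels: np.ndarray, predictions: np.ndarray, n_classes: int | None = None
) -> np.ndarray:
    """Row-normalized confusion matrix: each true-class row sums to 1.
    Rows of classes absent from ``labels`` are all zero."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have the same length")
    if n_classes is None:
        n_classes = int(max(labels.max(), predictions.max())) + 1
    cm = _sk_confusion(labels, predictions, labels=np.arange(n_classes)).astype(float)
    sums = cm.sum(axis=1, keepdims=True)
    return np.divide(cm, sums, out=np.zeros_like(cm), where=sums > 0)


def precision_sensitivity(
    labels: np.ndarray, predictions: np.ndarray, n_classes: int | None = None
) -> tuple[float, float]:
    """Macro-averaged precision and sensitivity (recall) across classes.
    A class never predicted has undefined precision; a class without
    support has undefined sensitivity; both are excluded with a warning."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have the same length")
    if n_classes is None:
        n_classes = int(max(labels.max(), predictions.max())) + 1
    precisions, recalls = [], []
    for c in range(n_classes):
        tp = int(((labels == c) & (predictions == c)).sum())
        pred_c = int((predictions == c).sum())
        true_c = int((labels == c).sum())
        if pred_c > 0:
            precisions.append(tp / pred_c)
        else:
            warnings.warn(f"class {c} never predicted; precision undefined", stacklevel=2)
        if true_c > 0:
            recalls.append(tp / true_c)
        else:
            warnings.warn(f"class {c} has no support; sensitivity undefined", stacklevel=2)
    return float(np.mean(precisions)), float(np.mean(recalls))
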