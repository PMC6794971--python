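"""Confusion matrix and per-class / macro precision-recall-F1 reporting.

Macro averages are unweighted means across classes.  A class with a zero
denominator (no support for recall, no predictions for precision) reports
0 for that metric together with an explicit flag, and flagged classes are
excluded from the corresponding macro average — never a NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CLASS_NAMES

__all__ = ["EvalReport", "confusion_matrix", "classification_report"]


def confusion_matrix(y_true, y_pred, n_classes: int = 5) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    return np.bincount(y_true * n_classes + y_pred,
                       minlength=n_classes * n_classes).reshape(n_classes, n_classes)


@dataclass
class EvalReport:
    """Per-class and macro classification metrics derived from a confusion matrix."""

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    #: classes whose recall (no support) / precision (no predictions) were
    #: undefined and reported as 0; excluded from the macro averages.
    undefined_recall: tuple[int, ...] = ()
    undefined_precision: tuple[int, ...] = ()
    class_names: tuple[str, ...] = CLASS_NAMES

    def to_frame(self) -> pd.DataFrame:
        """Metric table shaped like the published per-class reports."""
        rows = [{"metric": "accuracy", "value": self.accuracy}]
        for c, name in enumerate(self.class_names[: len(self.precision)]):
            rows += [
                {"metric": f"recall_{name}", "value": self.recall[c]},
                {"metric": f"precision_{name}", "value": self.precision[c]},
                {"metric": f"f1_{name}", "value": self.f1[c]},
            ]
        rows += [
            {"metric": "macro_recall", "value": self.macro_recall},
            {"metric": "macro_precision", "value": self.macro_precision},
            {"metric": "macro_f1", "value": self.macro_f1},
        ]
        return pd.DataFrame(rows)


def classification_report(confusion: np.ndarray) -> EvalReport:
    """Precision/recall/F1 per class plus unweighted macro averages."""
    cm = np.asarray(confusion, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or (cm < 0).any():
        raise ValueError("confusion matrix must be a square non-negative count matrix")
    k = cm.shape[0]
    diag = np.diag(cm).astype(np.float64)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    total = cm.sum()

    recall = np.divide(diag, support, out=np.zeros(k), where=support > 0)
    precision = np.divide(diag, predicted, out=np.zeros(k), where=predicted > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros(k), where=pr > 0)

    no_support = tuple(np.flatnonzero(support == 0).tolist())
    no_pred = tuple(np.flatnonzero(predicted == 0).tolist())
    rec_ok = support > 0
    pre_ok = predicted > 0
    f1_ok = rec_ok & pre_ok

    names = CLASS_NAMES if k == len(CLASS_NAMES) else tuple(f"class_{i}" for i in range(k))
    return EvalReport(
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        accuracy=float(diag.sum() / total) if total else 0.0,
        macro_recall=float(recall[rec_ok].mean()) if rec_ok.any() else 0.0,
        macro_precision=float(precision[pre_ok].mean()) if pre_ok.any() else 0.0,
        macro_f1=float(f1[f1_ok].mean()) if f1_ok.any() else 0.0,
        undefined_recall=no_support,
        undefined_precision=no_pred,
        class_names=names,
    )
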