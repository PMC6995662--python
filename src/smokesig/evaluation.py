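"""Classification metrics, cross-validation folds and ROC curves.

The positive class is the smoker class throughout, so sensitivity is the
smoker detection rate and specificity the nonsmoker detection rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ClassificationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: object = 1

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    def as_percent(self) -> dict[str, float]:
        """SN/SP/ACC as percentages rounded to one decimal (reporting style)."""
        return {
            "SN": round(100 * self.sensitivity, 1),
            "SP": round(100 * self.specificity, 1),
            "ACC": round(100 * self.accuracy, 1),
        }

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "positive_class": self.positive_class,
        }


def confusion(y_true, y_pred, positive_class=1) -> ClassificationMetrics:
    """Confusion counts and derived rates for a binary prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ClassificationMetrics(
        tp=int((pos_t & pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
        positive_class=positive_class,
    )


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded stratified fold assignment (array of fold ids, 0..k-1).

    Fold sizes differ by at most one and per-class proportions are preserved
    within one sample. Raises if any class has fewer than ``k`` members.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"each class must have >= k={k} samples; smallest class has {counts.min()}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        folds[test_idx] = f
    return folds


def roc_points(scores, y_true) -> tuple[pd.DataFrame, float]:
    """(FPR, TPR) threshold sweep and trapezoidal AUC.

    Equal scores are grouped at a single threshold. Requires both classes
    present.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes in y_true")
    fpr, tpr, thresholds = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}), auc


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a reporting table (layer, dataset role, n genes, SN/SP/ACC %)."""
    return pd.DataFrame(
        rows, columns=["layer", "dataset", "n_signature", "SN", "SP", "ACC"]
    )
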