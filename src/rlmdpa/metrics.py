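"""Confusion-matrix metrics and stratified cross-validation.

Six standard metrics for imbalanced binary screening: accuracy, recall,
precision, F-measure, specificity and G-means.  G-means is the geometric
mean sqrt(recall x specificity).  The positive class defaults to the
minority label (0); degenerate denominators yield 0 with a warning.

Cross-validation is stratified 5-fold; per-fold metrics are aggregated as
min / median / max / mean / std.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .env import LabeledImageSet
from .exceptions import DataError, InputError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "kfold_split",
    "cross_validate",
    "summarize_folds",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "recall", "precision", "f_measure", "specificity", "g_means")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    recall: float
    precision: float
    f_measure: float
    specificity: float
    g_means: float
    positive_class: int = 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(true_labels, predicted_labels, positive_class: int = 0) -> ConfusionCounts:
    """Count TP/TN/FP/FN with the given positive-class convention."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise InputError(f"label vectors disagree in shape: {y.shape} vs {p.shape}")
    pos = positive_class
    return ConfusionCounts(
        tp=int(np.sum((y == pos) & (p == pos))),
        tn=int(np.sum((y != pos) & (p != pos))),
        fp=int(np.sum((y != pos) & (p == pos))),
        fn=int(np.sum((y == pos) & (p != pos))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"degenerate denominator for {name}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts, positive_class: int = 0) -> MetricsReport:
    """The six screening metrics from confusion counts."""
    accuracy = _ratio(c.tp + c.tn, c.total, "accuracy")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    if recall + precision == 0.0:
        warnings.warn("degenerate denominator for f_measure; returning 0", stacklevel=2)
        f_measure = 0.0
    else:
        f_measure = 2.0 * recall * precision / (recall + precision)
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    g_means = math.sqrt(recall * specificity)
    return MetricsReport(
        accuracy=accuracy,
        recall=recall,
        precision=precision,
        f_measure=f_measure,
        specificity=specificity,
        g_means=g_means,
        positive_class=positive_class,
    )


def evaluate_predictions(true_labels, predicted_labels,
                         positive_class: int = 0) -> MetricsReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(true_labels, predicted_labels, positive_class),
                   positive_class)


def kfold_split(data: LabeledImageSet, k: int = 5, seed: int = 0):
    """Stratified folds as (train_idx, test_idx) pairs; seeded shuffling."""
    labels = data.labels
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise DataError(
            f"smallest class has {counts.min()} samples; cannot form {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(data)), labels))


def summarize_folds(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """min/median/max/mean/std per metric across folds."""
    table = pd.DataFrame([r.as_dict() for r in reports])
    summary = pd.DataFrame(
        {
            "min": table.min(),
            "median": table.median(),
            "max": table.max(),
            "mean": table.mean(),
            "std": table.std(ddof=1) if len(table) > 1 else 0.0 * table.iloc[0],
        }
    )
    summary.index.name = "metric"
    return summary


def cross_validate(
    data: LabeledImageSet,
    fit_predict: Callable[[LabeledImageSet, np.ndarray], np.ndarray],
    k: int = 5,
    seed: int = 0,
    positive_class: int = 0,
) -> tuple[list[MetricsReport], pd.DataFrame]:
    """k-fold evaluation of a train-then-predict pipeline.

    ``fit_predict(train_set, test_images)`` must return predicted labels
    for the test images.  Returns the per-fold reports and the
    min/median/max/mean/std summary table.
    """
    reports = []
    for train_idx, test_idx in kfold_split(data, k=k, seed=seed):
        train_set = data.subset(train_idx)
        test_set = data.subset(test_idx)
        predicted = np.asarray(fit_predict(train_set, test_set.images))
        reports.append(
            evaluate_predictions(test_set.labels, predicted, positive_class)
        )
    return reports, summarize_folds(reports)
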