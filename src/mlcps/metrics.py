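"""Binary-classification metric panel.

Computes the per-model evaluation metrics that feed the polygon score:
confusion-matrix metrics from hard predictions, ranking metrics (average
precision, ROC AUC) from continuous scores.  Every returned value lives on
[0, 1] so the panel satisfies the common-scale requirement of the composite
score; Matthews correlation is therefore only offered in the affinely
rescaled form (MCC + 1) / 2.

Metrics whose denominator vanishes (e.g. precision for a predictor that
never predicts positive) raise :class:`~mlcps.errors.UndefinedMetricError`
with a remediation hint rather than silently returning 0 or NaN — a silent
zero ray would drastically distort the downstream polygon area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .core import MetricVector
from .errors import InvalidMetricsError, UndefinedMetricError

__all__ = [
    "PredictionSet",
    "MetricPanel",
    "confusion_counts",
    "metric_panel",
    "rescale_unit_interval",
    "SUPPORTED_METRICS",
    "DEFAULT_PANEL",
]

SUPPORTED_METRICS = (
    "accuracy",
    "balanced_accuracy",
    "precision",
    "recall",
    "specificity",
    "f1",
    "mcc_rescaled",
    "average_precision",
    "roc_auc",
)

#: metrics needing continuous scores rather than hard predictions
SCORE_BASED = frozenset({"average_precision", "roc_auc"})

DEFAULT_PANEL = (
    "accuracy",
    "balanced_accuracy",
    "precision",
    "recall",
    "f1",
    "average_precision",
    "roc_auc",
)


def rescale_unit_interval(x, lower: float = -1.0, upper: float = 1.0):
    """Affinely map values from [lower, upper] onto [0, 1].

    Intended for metrics natively on [-1, 1] (Matthews correlation, Cohen's
    kappa) so they can join a panel of [0, 1] metrics on a common scale.
    """
    if not upper > lower:
        raise InvalidMetricsError("upper must exceed lower")
    return (np.asarray(x, dtype=float) - lower) / (upper - lower)


@dataclass(frozen=True)
class PredictionSet:
    """True labels, hard predictions and optional continuous scores.

    ``positive_label`` names which raw label value counts as positive; labels
    are mapped to {0, 1} internally.  ``y_score`` is required only for the
    ranking metrics (higher score = more positive).
    """

    y_true: np.ndarray
    y_pred: np.ndarray
    y_score: np.ndarray | None = None
    positive_label: object = 1

    def __init__(self, y_true, y_pred, y_score=None, positive_label=1):
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        if yt.shape != yp.shape or yt.ndim != 1:
            raise InvalidMetricsError(
                f"y_true and y_pred must be equal-length 1-D arrays, got "
                f"shapes {yt.shape} and {yp.shape}"
            )
        if yt.size == 0:
            raise InvalidMetricsError("empty prediction set")
        labels = set(np.unique(yt)) | set(np.unique(yp))
        if len(labels) > 2:
            raise InvalidMetricsError(
                f"labels must be binary; found {sorted(map(str, labels))}"
            )
        if positive_label not in labels:
            raise InvalidMetricsError(
                f"positive_label {positive_label!r} does not occur among "
                f"labels {sorted(map(str, labels))}"
            )
        yt01 = (yt == positive_label).astype(np.int8)
        yp01 = (yp == positive_label).astype(np.int8)
        if y_score is not None:
            ys = np.asarray(y_score, dtype=float)
            if ys.shape != yt.shape:
                raise InvalidMetricsError("y_score length mismatch")
            if not np.all(np.isfinite(ys)):
                raise InvalidMetricsError("y_score contains non-finite values")
            ys.setflags(write=False)
        else:
            ys = None
        yt01.setflags(write=False)
        yp01.setflags(write=False)
        object.__setattr__(self, "y_true", yt01)
        object.__setattr__(self, "y_pred", yp01)
        object.__setattr__(self, "y_score", ys)
        object.__setattr__(self, "positive_label", positive_label)

    def __len__(self) -> int:
        return int(self.y_true.size)


@dataclass(frozen=True)
class MetricPanel:
    """Named metric scores plus provenance notes (threshold, conventions)."""

    values: dict[str, float]
    notes: dict[str, str]

    def to_metric_vector(self) -> MetricVector:
        return MetricVector.from_dict(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def confusion_counts(preds: PredictionSet) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) — four non-negative ints summing to the sample count."""
    yt, yp = preds.y_true, preds.y_pred
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return tp, fp, tn, fn


def _ratio(num: float, den: float, metric: str, hint: str) -> float:
    if den == 0:
        raise UndefinedMetricError(
            f"{metric} is undefined (denominator is zero). {hint}"
        )
    return num / den


def metric_panel(
    preds: PredictionSet,
    metric_names: Sequence[str] | Iterable[str] = DEFAULT_PANEL,
) -> MetricPanel:
    """Compute the requested metrics from one model's predictions.

    Threshold metrics use the standard confusion-matrix definitions;
    ``average_precision`` uses the step-wise precision-weighted
    recall-increment rule and ``roc_auc`` the trapezoid rule with midpoint
    handling of score ties (constant scores give exactly 0.5).
    """
    names = list(metric_names)
    unknown = sorted(set(names) - set(SUPPORTED_METRICS))
    if unknown:
        raise InvalidMetricsError(
            f"unsupported metrics {unknown}; supported: {list(SUPPORTED_METRICS)}"
        )
    if any(m in SCORE_BASED for m in names) and preds.y_score is None:
        needed = sorted(set(names) & SCORE_BASED)
        raise InvalidMetricsError(
            f"metrics {needed} need continuous scores; provide y_score"
        )

    tp, fp, tn, fn = confusion_counts(preds)
    n = len(preds)
    pos, neg = tp + fn, tn + fp

    def recall() -> float:
        return _ratio(tp, pos, "recall",
                      "No positive instances in y_true; supply both classes.")

    def specificity() -> float:
        return _ratio(tn, neg, "specificity",
                      "No negative instances in y_true; supply both classes.")

    def precision() -> float:
        return _ratio(tp, tp + fp, "precision",
                      "The model never predicts the positive class; drop "
                      "precision from the panel or adjust the threshold.")

    values: dict[str, float] = {}
    for m in names:
        if m == "accuracy":
            values[m] = (tp + tn) / n
        elif m == "balanced_accuracy":
            values[m] = 0.5 * (recall() + specificity())
        elif m == "precision":
            values[m] = precision()
        elif m == "recall":
            values[m] = recall()
        elif m == "specificity":
            values[m] = specificity()
        elif m == "f1":
            p, r = precision(), recall()
            values[m] = _ratio(2 * p * r, p + r, "f1",
                               "Both precision and recall are zero.")
        elif m == "mcc_rescaled":
            den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            mcc = _ratio((tp * tn) - (fp * fn), den, "mcc_rescaled",
                         "A confusion-matrix margin is empty; MCC needs both "
                         "observed and predicted classes to vary.")
            values[m] = 0.5 * (mcc + 1.0)
        elif m == "average_precision":
            if pos == 0:
                raise UndefinedMetricError(
                    "average_precision is undefined without positive instances."
                )
            values[m] = float(average_precision_score(preds.y_true, preds.y_score))
        elif m == "roc_auc":
            if pos == 0 or neg == 0:
                raise UndefinedMetricError(
                    "roc_auc needs at least one instance of each class."
                )
            values[m] = float(roc_auc_score(preds.y_true, preds.y_score))

    notes = {
        "positive_label": repr(preds.positive_label),
        "roc_auc_ties": "midpoint (trapezoid) convention",
        "average_precision": "step-wise, non-interpolated",
    }
    return MetricPanel(values=values, notes=notes)
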