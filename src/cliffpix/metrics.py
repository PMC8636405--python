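"""Performance measures for cliff / non-cliff classification.

All measures are derived from the 2x2 confusion matrix with the cliff
(AC) class as positive:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1  = 2*TP / (2*TP + FP + FN)
    A   = (TP+TN) / (TP+TN+FP+FN)
    BA  = (TP/(TP+FN) + TN/(TN+FP)) / 2

plus the ROC curve and its area computed by a full threshold sweep with
trapezoidal integration (equivalently, the probability that a random
cliff scores above a random non-cliff, ties counted half).  A
single-threshold AUC surrogate, which algebraically equals balanced
accuracy, is provided for completeness but not used in reports.

Whenever a denominator is empty the affected measure is defined as 0 and
a warning is logged.  Aggregation over repeated trials reports the mean
and (by default sample, n-1) standard deviation per measure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, UsageError

logger = logging.getLogger(__name__)

POSITIVE = "AC"
NEGATIVE = "NON_AC"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise UsageError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    auc: float
    f1: float
    mcc: float
    accuracy: float
    balanced_accuracy: float
    roc_points: tuple[tuple[float, float], ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "f1": self.f1,
            "mcc": self.mcc,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Count the 2x2 table with AC as the positive class."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise UsageError("confusion: label vectors differ in length")
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t not in (POSITIVE, NEGATIVE) or p not in (POSITIVE, NEGATIVE):
            raise UsageError(f"confusion: unknown label in pair ({t!r}, {p!r})")
        if t == POSITIVE:
            tp += p == POSITIVE
            fn += p == NEGATIVE
        else:
            tn += p == NEGATIVE
            fp += p == POSITIVE
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s: empty denominator, returning 0", what)
        return 0.0
    return num / den


def mcc(c: ConfusionCounts) -> float:
    den = math.sqrt(
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    return _safe_div(float(c.tp) * c.tn - float(c.fp) * c.fn, den, "mcc")


def f1(c: ConfusionCounts) -> float:
    return _safe_div(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn, "f1")


def accuracy(c: ConfusionCounts) -> float:
    return _safe_div(float(c.tp + c.tn), float(c.total), "accuracy")


def accuracy_tp_fn_variant(c: ConfusionCounts) -> float:
    """(TP+FN)/total: the fraction of positives among all test pairs.

    Kept for reference only; it measures class prevalence rather than
    correctness and is not reported.
    """
    return _safe_div(float(c.tp + c.fn), float(c.total), "accuracy_tp_fn_variant")


def balanced_accuracy(c: ConfusionCounts) -> float:
    sens = _safe_div(float(c.tp), float(c.tp + c.fn), "sensitivity")
    spec = _safe_div(float(c.tn), float(c.tn + c.fp), "specificity")
    return 0.5 * (sens + spec)


def auc_single_point(c: ConfusionCounts) -> float:
    """Single-threshold AUC surrogate 1/2 - FPR/2 + TPR/2 (equals BA)."""
    fpr = _safe_div(float(c.fp), float(c.fp + c.tn), "auc_single_point")
    tpr = _safe_div(float(c.tp), float(c.tp + c.fn), "auc_single_point")
    return 0.5 - 0.5 * fpr + 0.5 * tpr


def roc_auc(scores, true_labels) -> tuple[float, list[tuple[float, float]]]:
    """Threshold-sweep ROC curve and trapezoidal AUC.

    ``scores`` are cliff-class probabilities (or any monotone score);
    ``true_labels`` are AC/NON_AC strings.  Tied scores contribute half
    a concordance, matching the Mann-Whitney convention.
    """
    scores = np.asarray(list(scores), dtype=np.float64)
    y = np.asarray([t == POSITIVE for t in true_labels], dtype=bool)
    if len(scores) != len(y):
        raise UsageError("roc_auc: scores and labels differ in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("roc_auc: need at least one member of each class")
    order = np.argsort(-scores, kind="stable")
    sorted_scores, sorted_y = scores[order], y[order]
    tps = np.cumsum(sorted_y)
    fps = np.cumsum(~sorted_y)
    # collapse tied-score runs so ties are handled by the trapezoid
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def report(
    true_labels, predicted_labels, scores
) -> MetricsReport:
    """All measures for one trial."""
    c = confusion(true_labels, predicted_labels)
    auc, points = roc_auc(scores, true_labels)
    return MetricsReport(
        auc=auc,
        f1=f1(c),
        mcc=mcc(c),
        accuracy=accuracy(c),
        balanced_accuracy=balanced_accuracy(c),
        roc_points=tuple(points),
    )


@dataclass(frozen=True)
class AggregateReport:
    mean: dict[str, float]
    sd: dict[str, float]
    n_trials: int


def aggregate(trial_reports, ddof: int = 1) -> AggregateReport:
    """Per-measure mean and standard deviation over repeated trials."""
    reports = list(trial_reports)
    if not reports:
        raise UsageError("aggregate: no trial reports")
    keys = reports[0].as_dict().keys()
    table = {k: np.array([r.as_dict()[k] for r in reports], dtype=float) for k in keys}
    eff_ddof = ddof if len(reports) > ddof else 0
    return AggregateReport(
        mean={k: float(v.mean()) for k, v in table.items()},
        sd={k: float(v.std(ddof=eff_ddof)) for k, v in table.items()},
        n_trials=len(reports),
    )


def reports_to_frame(trial_reports) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in trial_reports])
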