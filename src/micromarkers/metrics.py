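"""Classification metrics and ROC/AUC.

Accuracy, precision, recall and F1 are computed from raw confusion counts;
degenerate denominators (0/0) yield an explicit *undefined* marker (NaN)
rather than a silent zero, and are excluded from cross-validation
aggregation with a logged count.

AUC is the area under the ROC curve obtained by sweeping the score
threshold from high to low, integrated by the trapezoid rule.  With the
tie handling used here it equals the pairwise concordance probability
P(score_case > score_control) + 0.5 * P(tie).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: explicit marker for a metric whose denominator was zero
UNDEFINED = float("nan")


def is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass(frozen=True)
class ConfusionCounts:
    """Raw confusion-matrix counts; case = positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError(f"confusion counts must be non-negative, got {counts}")
        if sum(counts) < 1:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    """Evaluation metrics on [0, 1]; any entry may be UNDEFINED (NaN)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def classification_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall and F1 from confusion counts.

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

    A zero denominator yields UNDEFINED for that metric, never 0.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    accuracy = (tp + tn) / counts.total
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if is_undefined(precision) or is_undefined(recall):
        f1 = UNDEFINED
    else:
        f1 = _ratio(2.0 * precision * recall, precision + recall)
    return MetricSet(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def roc_auc(labels, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC.

    Thresholds sweep the distinct score values from high to low; tied
    scores advance TP and FP jointly, so the trapezoid rule gives ties a
    half-credit and the AUC equals the Mann-Whitney concordance statistic.

    Returns ``(roc_points, auc)`` where roc_points is a list of
    (false-positive rate, true-positive rate) pairs from (0, 0) to (1, 1).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-d and of equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos + n_neg != y.size:
        raise ValueError("labels must be binary {0, 1}")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group tied scores: cumulative TP/FP evaluated at the end of each tie block
    distinct = np.flatnonzero(np.diff(s_sorted)) # last index of each block but the final
    block_ends = np.r_[distinct, y_sorted.size - 1]
    cum_tp = np.cumsum(y_sorted == 1)[block_ends]
    cum_fp = np.cumsum(y_sorted == 0)[block_ends]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def aggregate_folds(per_fold: list[MetricSet]) -> dict[str, tuple[float, float]]:
    """Mean and sample standard deviation (ddof=1) per metric across folds.

    UNDEFINED fold values are excluded (count logged); a metric undefined
    in every fold aggregates to (UNDEFINED, UNDEFINED).
    """
    if len(per_fold) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    out: dict[str, tuple[float, float]] = {}
    names = ["accuracy", "precision", "recall", "f1"]
    if all(m.auc is not None for m in per_fold):
        names.append("auc")
    for name in names:
        vals = [getattr(m, name) for m in per_fold]
        defined = [v for v in vals if not is_undefined(v)]
        n_dropped = len(vals) - len(defined)
        if n_dropped:
            logger.warning("metric %r undefined in %d of %d folds; excluded "
                           "from aggregation", name, n_dropped, len(vals))
        if not defined:
            out[name] = (UNDEFINED, UNDEFINED)
        elif len(defined) == 1:
            out[name] = (defined[0], UNDEFINED)
        else:
            arr = np.asarray(defined)
            out[name] = (float(arr.mean()), float(arr.std(ddof=1)))
    return out
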