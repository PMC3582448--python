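"""Performance measurements: sensitivity, specificity, MCC, ROC curves, AUC.

The positive class throughout is "noncoding" (a lincRNA correctly called
non-coding is a true positive).  Percentages are reported rounded half-up to
one decimal; MCC and AUC to three decimals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from . import ValidationError
from .svm_model import LABEL_NONCODING, Prediction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) points from (0, 0) to (1, 1), both non-decreasing."""

    points: tuple[tuple[float, float], ...]


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up (matches how the reference tables print)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise ValidationError("sensitivity undefined: no positive instances")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    if c.tn + c.fp == 0:
        raise ValidationError("specificity undefined: no negative instances")
    return c.tn / (c.tn + c.fp)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (with a warning) on a zero marginal."""
    marginals = (
        (c.tp + c.fp),
        (c.tp + c.fn),
        (c.tn + c.fp),
        (c.tn + c.fn),
    )
    if any(m == 0 for m in marginals):
        logger.warning("MCC has a zero marginal; returning 0 by convention")
        return 0.0
    numerator = c.tp * c.tn - c.fp * c.fn
    denominator = math.sqrt(math.prod(float(m) for m in marginals))
    return numerator / denominator


def roc_curve(scores, labels) -> ROCCurve:
    """ROC points swept over distinct score thresholds, ties grouped.

    ``labels`` are 1/0 or 'noncoding'/'coding'; higher scores must favor the
    positive (noncoding) class.
    """
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape[0] != y.shape[0]:
        raise ValidationError("scores and labels differ in length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(np.sum(y_sorted[i:j] == 1))
        fp += int(np.sum(y_sorted[i:j] == 0))
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return ROCCurve(tuple(points))


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    area = 0.0
    pts = curve.points
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def auc_from_scores(scores, labels) -> float:
    """Rank-statistic (Mann-Whitney) AUC with midrank tie handling."""
    from scipy.stats import rankdata

    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(s)
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _as_binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        out = np.empty(arr.shape[0], dtype=int)
        for i, lab in enumerate(arr):
            if lab == "noncoding":
                out[i] = 1
            elif lab == "coding":
                out[i] = 0
            else:
                raise ValidationError(f"unknown class label {lab!r}")
        return out
    out = arr.astype(int)
    if not set(np.unique(out)) <= {0, 1}:
        raise ValidationError("numeric labels must be 0 or 1")
    return out


@dataclass(frozen=True)
class EvaluationReport:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    mcc: float
    auc: float | None

    def formatted(self) -> dict[str, float]:
        """Percentages to one decimal (half-up), MCC/AUC to three decimals."""
        out = {
            "sensitivity_pct": round_half_up(self.sensitivity * 100.0, 1),
            "specificity_pct": round_half_up(self.specificity * 100.0, 1),
            "mcc": round_half_up(self.mcc, 3),
        }
        if self.auc is not None:
            out["auc"] = round_half_up(self.auc, 3)
        return out


def confusion_from_predictions(
    predictions: list[Prediction], truth: dict[str, str]
) -> ConfusionCounts:
    missing = [p.transcript_id for p in predictions if p.transcript_id not in truth]
    if missing:
        raise ValidationError(
            f"{len(missing)} predicted ids missing from truth: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    tp = fp = tn = fn = 0
    for pred in predictions:
        actual_pos = truth[pred.transcript_id] == LABEL_NONCODING
        predicted_pos = pred.label == LABEL_NONCODING
        if actual_pos and predicted_pos:
            tp += 1
        elif actual_pos:
            fn += 1
        elif predicted_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_predictions(
    predictions: list[Prediction], truth: dict[str, str]
) -> EvaluationReport:
    """Full report: confusion counts, Eqs for sens/spec/MCC, and score AUC."""
    counts = confusion_from_predictions(predictions, truth)
    scores = [p.noncoding_score for p in predictions]
    labels = [truth[p.transcript_id] for p in predictions]
    try:
        auc_value: float | None = auc_from_scores(scores, labels)
    except ValidationError:
        auc_value = None
    return EvaluationReport(
        counts=counts,
        sensitivity=sensitivity(counts),
        specificity=specificity(counts),
        mcc=mcc(counts),
        auc=auc_value,
    )
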