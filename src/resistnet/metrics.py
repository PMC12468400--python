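"""Binary classification metrics with the resistant class as positive.

Threshold metrics come from the confusion counts in closed form (with a
zero-denominator flag rather than NaN); ranking metrics (ROC/PRC) delegate
to scikit-learn's curve constructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

__all__ = ["MetricBundle", "confusion", "classification_metrics", "roc_prc", "metric_bundle"]

POSITIVE_CLASS = "resistant"


@dataclass
class MetricBundle:
    auc: float
    mcc: float
    f1: float
    recall: float
    accuracy: float
    precision: float
    n: int
    tp: int
    fp: int
    fn: int
    tn: int
    roc_points: np.ndarray | None = None
    prc_points: np.ndarray | None = None
    average_precision: float | None = None
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("auc", "mcc", "f1", "recall", "accuracy", "precision", "n", "tp", "fp", "fn", "tn")
        }
        d["average_precision"] = self.average_precision
        return d


def _to_binary(a) -> np.ndarray:
    a = np.asarray(a)
    if a.dtype.kind in "UOS":
        return (a == POSITIVE_CLASS).astype(int)
    return a.astype(int)


def confusion(labels, predictions) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) with resistant (or 1) as the positive class."""
    y = _to_binary(labels)
    p = _to_binary(predictions)
    if len(y) != len(p):
        raise ValueError("labels and predictions must have equal length")
    if len(y) == 0:
        raise ValueError("empty input")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    return tp, fp, fn, tn


def classification_metrics(counts: tuple[int, int, int, int]) -> MetricBundle:
    """Threshold metrics from confusion counts; 0 with a flag on empty
    denominators."""
    tp, fp, fn, tn = counts
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("no observations")
    degenerate: list[str] = []

    def safe(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    accuracy = (tp + tn) / n
    f1 = safe(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricBundle(
        auc=float("nan"),
        mcc=mcc,
        f1=f1,
        recall=recall,
        accuracy=accuracy,
        precision=precision,
        n=n,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        degenerate=degenerate,
    )


def roc_prc(scores, labels):
    """ROC and PRC constructions over all score thresholds.

    Returns (auc, roc_points, prc_points, average_precision); points are
    (x, y, threshold) arrays. AUC is the trapezoidal area under ROC.
    """
    y = _to_binary(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    prec, rec, pthr = precision_recall_curve(y, s)
    ap = float(average_precision_score(y, s))
    roc_points = np.column_stack([fpr, tpr, thr])
    prc_points = np.column_stack([rec, prec, np.append(pthr, np.inf)])
    return auc, roc_points, prc_points, ap


def metric_bundle(labels, scores, threshold: float = 0.5) -> MetricBundle:
    """Full bundle: threshold metrics at ``score > threshold`` plus curves."""
    y = _to_binary(labels)
    s = np.asarray(scores, dtype=float)
    preds = (s > threshold).astype(int)
    bundle = classification_metrics(confusion(y, preds))
    if len(np.unique(y)) == 2:
        auc, roc_points, prc_points, ap = roc_prc(s, y)
        bundle.auc = auc
        bundle.roc_points = roc_points
        bundle.prc_points = prc_points
        bundle.average_precision = ap
    else:
        bundle.degenerate.append("auc")
    return bundle
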