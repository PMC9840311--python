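"""ROC/AUC, confusion matrices, and sensitivity at fixed specificity.

Conventions: a sample is predicted positive iff its score is >= the cutoff;
undefined rates (0/0) are reported as None, never 0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import TUMOR


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels, positive: str = TUMOR) -> RocCurve:
    """ROC curve and AUC; AUC equals the Mann-Whitney concordance
    probability (tied cross-class pairs counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == positive).astype(int)
    if y.min() == y.max():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thr, fpr, tpr, auc)


@dataclass
class ConfusionResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None


def _rate(num: int, den: int) -> float | None:
    return num / den if den else None


def confusion_at(scores, labels, cutoff: float, positive: str = TUMOR) -> ConfusionResult:
    """Confusion counts and derived rates at a fixed cutoff."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    pred = scores >= cutoff
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    return ConfusionResult(
        tp, fp, tn, fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        accuracy=_rate(tp + tn, tp + fp + tn + fn),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
    )


@dataclass
class SensAtSpecResult:
    sensitivity: float
    cutoff: float
    achieved_specificity: float
    unreachable: bool = False


def sensitivity_at_specificity(
    scores,
    labels,
    target_specificity: float = 0.98,
    subgroup_mask=None,
    positive: str = TUMOR,
) -> SensAtSpecResult:
    """Sensitivity at the smallest cutoff whose specificity >= target.

    Specificity always uses ALL controls; with ``subgroup_mask`` the
    sensitivity is restricted to positive samples inside the mask (e.g., a
    simulated early-stage stratum).  If no cutoff reaches the target the
    result is flagged with cutoff = +inf and sensitivity 0.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pos_mask = y if subgroup_mask is None else (y & np.asarray(subgroup_mask, dtype=bool))
    neg = scores[~y]
    for c in np.sort(np.unique(scores)):
        spec = float((neg < c).mean())
        if spec >= target_specificity:
            sens = float((scores[pos_mask] >= c).mean()) if pos_mask.any() else float("nan")
            return SensAtSpecResult(sens, float(c), spec)
    return SensAtSpecResult(0.0, float("inf"), 1.0, unreachable=True)
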