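"""Evaluation: precision/recall/F1, ROC curves, paired significance tests.

The positive class is DDI throughout.  Zero-denominator conventions follow
the shared-task evaluation style: with no predicted positives P = 0 (and
hence F1 = 0); with no gold positives R = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

DDI = "DDI"

__all__ = ["PRF", "RocCurve", "precision_recall_f1", "roc_points", "paired_t_test"]


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def precision_recall_f1(pred, gold, positive: str = DDI) -> PRF:
    pred = list(pred)
    gold = list(gold)
    if len(pred) != len(gold):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(gold)} gold labels")
    tp = sum(1 for p, g in zip(pred, gold) if p == positive and g == positive)
    fp = sum(1 for p, g in zip(pred, gold) if p == positive and g != positive)
    fn = sum(1 for p, g in zip(pred, gold) if p != positive and g == positive)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return PRF(precision, recall, f1, tp, fp, fn)


def roc_points(scores, gold, positive: str = DDI) -> RocCurve:
    """ROC by threshold sweep over the distinct scores (equal scores grouped),
    AUC by the trapezoid rule; endpoints are exactly (0,0) and (1,1)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if g == positive else 0 for g in gold])
    if y.min() == y.max():
        raise ValueError("ROC needs at least one positive and one negative gold label")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    auc = float(roc_auc_score(y, scores))
    return RocCurve(fpr, tpr, thr, auc)


def paired_t_test(per_unit_a, per_unit_b) -> tuple[float, float, bool]:
    """Two-sided paired t-test on per-unit metric differences.

    Returns (t, p, significant at p < 0.05).  Identical lists give t = 0,
    p = 1; a constant non-zero difference has zero variance and is reported
    as t = +-inf, p = 0 with a warning.
    """
    a = np.asarray(per_unit_a, dtype=float)
    b = np.asarray(per_unit_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1-d metric lists")
    if len(a) < 2:
        raise ValueError("paired test needs at least two paired units")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0, False
        warnings.warn(
            "zero-variance differences; reporting t = +-inf", RuntimeWarning
        )
        t = float(np.inf if diff.mean() > 0 else -np.inf)
        return t, 0.0, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), bool(p < 0.05)
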