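"""Multi-label evaluation metrics and label-distribution comparison.

Micro scores pool true/false positives and negatives over every (instance,
label) cell; macro scores average per-label scores unweighted, skipping
labels with no positive ground truth (the skip count is reported, since
this convention changes macro values on rare labels).  AUROC is computed
per label from the rank statistic (midrank ties) and macro-averaged over
labels where both classes occur.  The two-sample Kolmogorov-Smirnov test
compares two vectors of per-label proportions, e.g. a full dataset against
a subset, to check the subset is representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvaluationReport",
    "micro_scores",
    "macro_scores",
    "auroc_macro",
    "ks_compare",
    "evaluate",
    "label_proportions",
]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.atleast_2d(np.asarray(a))
    b = np.atleast_2d(np.asarray(b))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def micro_scores(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float]:
    """(precision, recall, F1) pooled over all label cells; 0 on zero division."""
    y_true, y_pred = _check_shapes(y_true, y_pred)
    tp = float(((y_true == 1) & (y_pred == 1)).sum())
    fp = float(((y_true == 0) & (y_pred == 1)).sum())
    fn = float(((y_true == 1) & (y_pred == 0)).sum())
    if tp + fp == 0 or tp + fn == 0:
        warnings.warn("zero division in micro scores", UserWarning, stacklevel=2)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def _per_label_scores(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-label (precision, recall, F1) with zero division mapped to 0."""
    tp = ((y_true == 1) & (y_pred == 1)).sum(axis=0).astype(float)
    fp = ((y_true == 0) & (y_pred == 1)).sum(axis=0).astype(float)
    fn = ((y_true == 1) & (y_pred == 0)).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        r = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
    return p, r, f


def macro_scores(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float, int]:
    """Unweighted per-label average of (precision, recall, F1).

    Labels with zero positive ground truth are skipped; the count of
    skipped labels is returned as the fourth element.
    """
    y_true, y_pred = _check_shapes(y_true, y_pred)
    support = y_true.sum(axis=0)
    keep = support > 0
    n_skipped = int((~keep).sum())
    if not keep.any():
        warnings.warn("no labels with positive support", UserWarning, stacklevel=2)
        return 0.0, 0.0, 0.0, n_skipped
    p, r, f = _per_label_scores(y_true[:, keep], y_pred[:, keep])
    return float(p.mean()), float(r.mean()), float(f.mean()), n_skipped


def auroc_macro(y_true: np.ndarray, y_prob: np.ndarray) -> tuple[float, int]:
    """Macro-averaged ROC AUC over labels with both classes present.

    Returns (auroc, n_labels_skipped); NaN if no label has both classes.
    """
    y_true, y_prob = _check_shapes(y_true, y_prob)
    aucs = []
    skipped = 0
    for j in range(y_true.shape[1]):
        col = y_true[:, j]
        if col.min() == col.max():
            skipped += 1
            continue
        aucs.append(roc_auc_score(col, y_prob[:, j]))
    if not aucs:
        return float("nan"), skipped
    return float(np.mean(aucs)), skipped


def label_proportions(Y: np.ndarray) -> np.ndarray:
    """Fraction of instances carrying each label."""
    Y = np.asarray(Y)
    return Y.mean(axis=0)


def ks_compare(props_a: np.ndarray, props_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on per-label proportion vectors.

    Returns the statistic D = sup |ECDF_a - ECDF_b| and the asymptotic
    p-value.  Identical vectors give D = 0, p = 1.
    """
    props_a = np.asarray(props_a, dtype=float).ravel()
    props_b = np.asarray(props_b, dtype=float).ravel()
    if props_a.size == 0 or props_b.size == 0:
        raise ValueError("proportion vectors must be non-empty")
    res = stats.ks_2samp(props_a, props_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvaluationReport:
    """All headline metrics for one (truth, prediction) pair."""

    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_label_f1: np.ndarray
    auroc: float
    n_labels_skipped: int

    def to_dict(self) -> dict:
        return {
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "auroc": self.auroc,
            "n_labels_skipped": self.n_labels_skipped,
        }


def evaluate(
    y_true: np.ndarray,
    y_prob: np.ndarray,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Evaluate probability predictions against a binary truth matrix."""
    y_true, y_prob = _check_shapes(y_true, y_prob)
    y_pred = (y_prob >= threshold).astype(np.int8)
    mp, mr, mf = micro_scores(y_true, y_pred)
    Mp, Mr, Mf, n_skip_macro = macro_scores(y_true, y_pred)
    _, _, per_label = _per_label_scores(y_true, y_pred)
    auc, n_skip_auc = auroc_macro(y_true, y_prob)
    return EvaluationReport(
        micro_precision=mp,
        micro_recall=mr,
        micro_f1=mf,
        macro_precision=Mp,
        macro_recall=Mr,
        macro_f1=Mf,
        per_label_f1=np.asarray(per_label),
        auroc=auc,
        n_labels_skipped=max(n_skip_macro, n_skip_auc),
    )
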