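"""Imbalance measures for multi-label datasets.

For a binary label matrix ``Y`` the per-label imbalance ratio IRLbl(y) is the
positive count of the most frequent label divided by the positive count of
label y, so the majority label scores exactly 1 and rarer labels score
higher.  MeanIR averages IRLbl over labels; CVIR is the coefficient of
variation of IRLbl (sample standard deviation, divisor |Y|-1, over MeanIR)
and separates datasets where all labels are similarly imbalanced from
datasets with a few extreme labels.  Card is the mean number of labels per
instance and Dens is Card normalised by the number of labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImbalanceReport",
    "irlbl",
    "mean_ir",
    "max_ir",
    "cvir",
    "card_dens",
    "imbalance_report",
]


def _label_counts(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-D binary matrix")
    return Y.sum(axis=0).astype(float)


def irlbl(Y: np.ndarray, on_zero: str = "exclude") -> np.ndarray:
    """Per-label imbalance ratio: max label count / label count.

    Labels with zero positives (possible after splitting or undersampling)
    yield an infinite ratio; by default they are excluded with a warning and
    marked NaN in the returned vector so positions stay aligned.

    Parameters
    ----------
    Y : binary matrix (n, L)
    on_zero : "exclude" or "error"
        How to treat zero-positive labels.

    Returns
    -------
    ndarray of length L; NaN where a label was excluded.
    """
    counts = _label_counts(Y)
    if counts.size == 0:
        raise ValueError("Y has no labels")
    zero = counts == 0
    if zero.any():
        if on_zero == "error":
            raise ValueError(
                f"{int(zero.sum())} label(s) have zero positives"
            )
        warnings.warn(
            f"excluding {int(zero.sum())} zero-positive label(s) from IRLbl",
            UserWarning,
            stacklevel=2,
        )
    if zero.all():
        raise ValueError("all labels have zero positives")
    out = np.full(counts.shape, np.nan)
    nz = ~zero
    out[nz] = counts[nz].max() / counts[nz]
    return out


def mean_ir(Y: np.ndarray) -> float:
    """Mean of IRLbl over labels (zero-positive labels excluded)."""
    v = irlbl(Y)
    return float(np.nanmean(v))


def max_ir(Y: np.ndarray) -> float:
    v = irlbl(Y)
    return float(np.nanmax(v))


def cvir(Y: np.ndarray) -> float:
    """Coefficient of variation of IRLbl: sd(IRLbl, ddof=1) / MeanIR."""
    v = irlbl(Y)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("CVIR is undefined for fewer than two labels")
    return float(np.std(v, ddof=1) / np.mean(v))


def card_dens(Y: np.ndarray) -> tuple[float, float]:
    """(Card, Dens): mean labels per instance and Card / number of labels."""
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.size == 0:
        raise ValueError("Y must be a non-empty 2-D binary matrix")
    card = float(Y.sum(axis=1).mean())
    return card, card / Y.shape[1]


@dataclass
class ImbalanceReport:
    """All imbalance measures for one label matrix."""

    card: float
    dens: float
    irlbl: np.ndarray
    mean_ir: float
    max_ir: float
    cvir: float
    n_labels_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "Card": self.card,
            "Dens": self.dens,
            "CVIR": self.cvir,
            "MaxIR": self.max_ir,
            "MeanIR": self.mean_ir,
            "n_labels_excluded": self.n_labels_excluded,
        }


def imbalance_report(Y: np.ndarray) -> ImbalanceReport:
    """Compute Card, Dens, IRLbl, MeanIR, MaxIR and CVIR for ``Y``."""
    v = irlbl(Y)
    card, dens = card_dens(Y)
    finite = v[~np.isnan(v)]
    return ImbalanceReport(
        card=card,
        dens=dens,
        irlbl=v,
        mean_ir=float(np.mean(finite)),
        max_ir=float(np.max(finite)),
        cvir=float(np.std(finite, ddof=1) / np.mean(finite))
        if finite.size > 1
        else 0.0,
        n_labels_excluded=int(np.isnan(v).sum()),
    )
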