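"""Random multi-label resampling and stratified splitting.

Multi-label random oversampling (ML-ROS) clones instances that carry a
*minority* label — one whose per-label imbalance ratio IRLbl exceeds the
dataset MeanIR — until the dataset has grown by P percent.  Multi-label
random undersampling (ML-RUS) deletes instances that carry *no* minority
label until the dataset has shrunk by P percent, so minority-label positives
are never removed.  Both refresh IRLbl/MeanIR as they go (every
``recompute_every`` edits, default after every single clone/deletion), so a
label that crosses MeanIR stops driving resampling.

The iterative stratified splitter assigns instances greedily, rarest label
first, toward per-split desired label counts — preserving per-label
train/test proportions far better than a uniform random split when labels
are long-tailed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import MultiLabelDataset
from .imbalance import irlbl

__all__ = [
    "ResampleConfig",
    "ml_ros",
    "ml_rus",
    "resample",
    "iterative_split_indices",
    "iterative_stratified_split",
]


@dataclass
class ResampleConfig:
    """mode: "ROS" (oversample) or "RUS" (undersample); percentage: P% of
    |D| instances to clone/delete; recompute_every: edits between
    IRLbl/MeanIR refreshes (1 = refresh after every edit)."""

    mode: str = "ROS"
    percentage: float = 10.0
    seed: int = 0
    recompute_every: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("ROS", "RUS"):
            raise ValueError("mode must be 'ROS' or 'RUS'")
        if self.percentage <= 0:
            raise ValueError("percentage must be positive")
        if self.recompute_every < 1:
            raise ValueError("recompute_every must be >= 1")


def _minority_labels(Y: np.ndarray) -> np.ndarray:
    """Indices of labels with IRLbl strictly above MeanIR (NaN-safe)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        v = irlbl(Y)
    mean = np.nanmean(v)
    out = np.flatnonzero(v > mean)
    return out


def _rebuild(D: MultiLabelDataset, src: list[int], ids: list[str]) -> MultiLabelDataset:
    idx = np.asarray(src)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return MultiLabelDataset(
            X=D.X[idx].copy(),
            Y=D.Y[idx].copy(),
            label_names=list(D.label_names),
            ids=ids,
        )


def ml_ros(D: MultiLabelDataset, cfg: ResampleConfig) -> MultiLabelDataset:
    """Multi-label random oversampling: clone minority-label instances.

    Appends exactly ``floor(|D| * P / 100)`` clones (fewer, with a warning,
    if every label rebalances first).  Each clone copies an instance drawn
    uniformly from the bag of (instance, current-minority-label) pairs, so
    instances carrying several minority labels are proportionally more
    likely to be cloned; clone ids get a ``.cN`` suffix.  Never deletes.
    Deterministic given ``cfg.seed``.
    """
    if D.n_instances == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    quota = int(D.n_instances * cfg.percentage / 100)
    src = list(range(D.n_instances))  # row -> original instance index
    ids = list(D.ids)
    minority = _minority_labels(D.Y)
    if minority.size == 0:
        warnings.warn(
            "no minority labels (IRLbl > MeanIR); dataset returned unchanged",
            UserWarning,
            stacklevel=2,
        )
        return _rebuild(D, src, ids)

    cloned = 0
    since_refresh = 0
    while cloned < quota and minority.size:
        Y_cur = D.Y[np.asarray(src)]
        membership = Y_cur[:, minority]  # rows x minority labels
        total = int(membership.sum())
        if total == 0:
            break
        pick = int(rng.integers(total))
        # locate the pick-th (row, label) pair in column-major label order
        col_counts = membership.sum(axis=0)
        col = 0
        while pick >= col_counts[col]:
            pick -= int(col_counts[col])
            col += 1
        row = int(np.flatnonzero(membership[:, col])[pick])
        base = ids[row].split(".c")[0]
        src.append(src[row])
        ids.append(f"{base}.c{cloned}")
        cloned += 1
        since_refresh += 1
        if since_refresh >= cfg.recompute_every:
            minority = _minority_labels(D.Y[np.asarray(src)])
            since_refresh = 0
    if cloned < quota:
        warnings.warn(
            f"ML-ROS stopped after {cloned}/{quota} clones: no minority "
            "labels remain",
            UserWarning,
            stacklevel=2,
        )
    return _rebuild(D, src, ids)


def ml_rus(D: MultiLabelDataset, cfg: ResampleConfig) -> MultiLabelDataset:
    """Multi-label random undersampling: delete majority-only instances.

    Removes ``floor(|D| * P / 100)`` instances drawn uniformly from those
    carrying no current minority label; minority-label instances are
    protected and never deleted, so minority positive counts are preserved.
    If the quota cannot be met, deletes as many as possible and warns.
    Deterministic given ``cfg.seed``.
    """
    if D.n_instances == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    quota = int(D.n_instances * cfg.percentage / 100)
    src = list(range(D.n_instances))
    ids = list(D.ids)
    deleted = 0
    since_refresh = 0
    minority = _minority_labels(D.Y)
    while deleted < quota:
        Y_cur = D.Y[np.asarray(src)]
        protected = Y_cur[:, minority].any(axis=1) if minority.size else np.zeros(
            len(src), dtype=bool
        )
        deletable = np.flatnonzero(~protected)
        if deletable.size == 0:
            break
        row = int(rng.choice(deletable))
        del src[row]
        del ids[row]
        deleted += 1
        since_refresh += 1
        if since_refresh >= cfg.recompute_every:
            minority = _minority_labels(D.Y[np.asarray(src)])
            since_refresh = 0
    if deleted < quota:
        warnings.warn(
            f"ML-RUS removed {deleted}/{quota} instances: remaining "
            "instances all carry a minority label",
            UserWarning,
            stacklevel=2,
        )
    return _rebuild(D, src, ids)


def resample(D: MultiLabelDataset, cfg: ResampleConfig) -> MultiLabelDataset:
    """Dispatch to :func:`ml_ros` or :func:`ml_rus` per ``cfg.mode``."""
    return ml_ros(D, cfg) if cfg.mode == "ROS" else ml_rus(D, cfg)


def iterative_split_indices(
    Y: np.ndarray,
    fractions: tuple[float, ...] = (0.8, 0.2),
    seed: int = 0,
) -> list[np.ndarray]:
    """Greedy iterative stratification of a label matrix into splits.

    Desired per-split label counts are ``fractions[s] * count(label)``.
    Labels are processed rarest-first; each instance carrying the current
    label goes to the split whose desired count for that label is greatest,
    ties broken by the split with the greatest total remaining capacity,
    then by seeded RNG.  Instances left with no labels are placed by total
    remaining capacity.  Returns one index array per split.
    """
    Y = np.asarray(Y)
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    if (fractions <= 0).any():
        raise ValueError("fractions must be positive")
    rng = np.random.default_rng(seed)
    n, L = Y.shape
    n_splits = fractions.size

    counts = Y.sum(axis=0).astype(float)
    if (counts == 1).any():
        warnings.warn(
            f"{int((counts == 1).sum())} label(s) have a single positive; "
            "they go to the largest split",
            UserWarning,
            stacklevel=2,
        )
    desired_label = fractions[:, None] * counts[None, :]  # splits x labels
    desired_total = fractions * n
    remaining = np.ones(n, dtype=bool)
    assignment = np.full(n, -1)
    Y_rem = Y.copy().astype(bool)

    while remaining.any():
        rem_counts = Y_rem[remaining].sum(axis=0)
        active = np.flatnonzero(rem_counts > 0)
        if active.size == 0:
            # no labels left: place leftovers by total remaining capacity
            for i in np.flatnonzero(remaining):
                s = _argmax_tiebreak(desired_total, rng)
                assignment[i] = s
                desired_total[s] -= 1
                remaining[i] = False
            break
        lab = active[np.argmin(rem_counts[active])]
        members = np.flatnonzero(remaining & Y_rem[:, lab])
        rng.shuffle(members)
        for i in members:
            cand = desired_label[:, lab]
            best = np.flatnonzero(cand == cand.max())
            if best.size > 1:
                tot = desired_total[best]
                best = best[np.flatnonzero(tot == tot.max())]
                s = int(rng.choice(best)) if best.size > 1 else int(best[0])
            else:
                s = int(best[0])
            assignment[i] = s
            remaining[i] = False
            desired_label[s, Y[i].astype(bool)] -= 1
            desired_total[s] -= 1
    return [np.flatnonzero(assignment == s) for s in range(n_splits)]


def _argmax_tiebreak(values: np.ndarray, rng: np.random.Generator) -> int:
    best = np.flatnonzero(values == values.max())
    return int(rng.choice(best)) if best.size > 1 else int(best[0])


def iterative_stratified_split(
    D: MultiLabelDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[MultiLabelDataset, MultiLabelDataset]:
    """Split a dataset into (train, test) by iterative stratification.

    Deterministic given ``seed``.  Per-label proportions in train and test
    track the global proportions far more closely than a uniform random
    split; a label with a single positive lands in train (the larger split).
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    train_idx, test_idx = iterative_split_indices(
        D.Y, fractions=(1 - test_fraction, test_fraction), seed=seed
    )
    return D.subset(train_idx), D.subset(test_idx)
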