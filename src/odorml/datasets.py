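"""Common in-memory containers for the odor multi-label pipeline.

The pipeline's common currency is a :class:`MultiLabelDataset`: a real-valued
feature matrix ``X`` (molecules x descriptors) paired with a binary label
matrix ``Y`` (molecules x odor labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MultiLabelDataset"]


@dataclass
class MultiLabelDataset:
    """A feature matrix plus a binary odor-label matrix.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Real-valued features (smoothed spectra, binned mass spectra,
        fingerprint bits, or their concatenation).
    Y : ndarray of shape (n, L)
        Binary label matrix; ``Y[i, j] = 1`` iff molecule *i* carries odor
        label *j*.
    label_names : list of str
        One name per label column.
    ids : list of str
        Molecule identifiers, one per row. Clones produced by oversampling
        carry a ``.cN`` suffix so provenance stays traceable.
    """

    X: np.ndarray
    Y: np.ndarray
    label_names: list[str] = field(default_factory=list)
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D matrices")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        vals = np.unique(self.Y)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("Y must be binary (0/1)")
        self.Y = self.Y.astype(np.int8)
        if not self.label_names:
            self.label_names = [f"label_{j}" for j in range(self.Y.shape[1])]
        if len(self.label_names) != self.Y.shape[1]:
            raise ValueError("label_names length must match Y columns")
        if not self.ids:
            self.ids = [f"mol_{i}" for i in range(self.X.shape[0])]
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids length must match number of rows")
        if self.Y.shape[0] and (self.Y.sum(axis=1) == 0).any():
            warnings.warn(
                "some instances carry no label", UserWarning, stacklevel=2
            )

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_labels(self) -> int:
        return self.Y.shape[1]

    def subset(self, idx: np.ndarray | list[int]) -> "MultiLabelDataset":
        """Row-subset (copy) keeping labels and ids aligned."""
        idx = np.asarray(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return MultiLabelDataset(
                X=self.X[idx].copy(),
                Y=self.Y[idx].copy(),
                label_names=list(self.label_names),
                ids=[self.ids[i] for i in idx],
            )

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Y, index=self.ids, columns=self.label_names)
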