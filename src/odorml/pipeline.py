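"""Convenience glue: featurize a whole study into a MultiLabelDataset."""

from __future__ import annotations

import numpy as np

from .datasets import MultiLabelDataset
from .featurize import SmoothingConfig, fuse_features, smooth_vibrational, window_mass_spectrum
from .synth import SyntheticStudy

__all__ = ["featurize_study", "study_to_dataset"]


def featurize_study(
    study: SyntheticStudy,
    smoothing: SmoothingConfig | None = None,
    modalities: tuple[str, ...] = ("vs", "ms", "fp"),
) -> np.ndarray:
    """Fused feature matrix for a study; modalities in the given order."""
    smoothing = smoothing or SmoothingConfig()
    blocks = []
    for m in modalities:
        if m == "vs":
            blocks.append(
                np.vstack(
                    [smooth_vibrational(p, smoothing).values for p in study.vs_peaks]
                )
            )
        elif m == "ms":
            blocks.append(
                np.vstack([window_mass_spectrum(p).values for p in study.ms_peaks])
            )
        elif m == "fp":
            blocks.append(study.fingerprints.astype(float))
        else:
            raise ValueError(f"unknown modality {m!r}")
    fused, _ = fuse_features(blocks)
    return fused


def study_to_dataset(
    study: SyntheticStudy,
    smoothing: SmoothingConfig | None = None,
    modalities: tuple[str, ...] = ("vs", "ms", "fp"),
) -> MultiLabelDataset:
    """Featurize a study and wrap it as a MultiLabelDataset."""
    X = featurize_study(study, smoothing=smoothing, modalities=modalities)
    return MultiLabelDataset(
        X=X, Y=study.labels, label_names=list(study.label_names)
    )
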