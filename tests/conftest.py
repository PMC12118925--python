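"""Shared fixtures: small planted-signal studies reused across test modules.

The expensive fixtures (a trained cost-sensitive MLP on noiseless planted
data) are session-scoped so the recovery checks in the model, attribution
and acceptance suites share one training run.
"""

import pytest

from odorml import (
    FocalLossParams,
    MultiLabelDataset,
    SynthConfig,
    TrainConfig,
    train_csmlp,
)
from odorml.evaluation import evaluate
from odorml.pipeline import featurize_study
from odorml.resampling import iterative_stratified_split
from odorml.synth import generate_study


@pytest.fixture(scope="session")
def planted_study():
    """Noiseless planted-signal study: labels fully determine the features."""
    cfg = SynthConfig(
        n_molecules=600,
        n_labels=20,
        cardinality_target=2.5,
        head_frequency=0.27,
        tail_frequency=0.01,
        signal_strength=1.0,
        noise_peaks=0,
        seed=7,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def planted_dataset(planted_study):
    X = featurize_study(planted_study)
    return MultiLabelDataset(
        X=X, Y=planted_study.labels, label_names=planted_study.label_names
    )


@pytest.fixture(scope="session")
def recovery_run(planted_dataset):
    """Train/test split + trained CSMLP + held-out evaluation on noiseless
    planted data; the central parameter-recovery artifact."""
    train, test = iterative_stratified_split(planted_dataset, 0.2, seed=0)
    model = train_csmlp(
        train,
        TrainConfig(epochs=30, hidden=(128, 64), batch_size=32, seed=0),
        FocalLossParams(gamma=2.0),
    )
    proba, pred = model.predict(test.X)
    report = evaluate(test.Y, proba)
    return {
        "train": train,
        "test": test,
        "model": model,
        "proba": proba,
        "pred": pred,
        "report": report,
    }
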