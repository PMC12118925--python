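"""Focal loss, the cost-sensitive MLP, and the decomposition classifiers."""

import warnings

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from odorml import MultiLabelDataset
from odorml.models import (
    BinaryRelevanceModel,
    ClassifierChainModel,
    FocalLossParams,
    TrainConfig,
    focal_loss,
    predict,
    train_binary_relevance,
    train_classifier_chain,
    train_csmlp,
    train_random_forest,
)


def bce(y, p, eps):
    """Independent binary cross-entropy oracle (sum labels, mean rows)."""
    y = np.atleast_2d(np.asarray(y, float))
    p = np.atleast_2d(np.asarray(p, float))
    return float(
        -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).sum(1).mean()
    )


class TestFocalLoss:
    def test_hand_value_single_cell(self):
        # y=1, p=0.5, gamma=2: (1-0.5)^2 * ln 2 = 0.25 * 0.6931
        val = focal_loss(
            np.array([[1.0]]),
            np.array([[0.5]]),
            FocalLossParams(gamma=2.0, epsilon=1e-9),
        )
        assert val == pytest.approx(0.25 * np.log(2), abs=1e-6)

    def test_gamma_zero_equals_bce_to_1e10(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, (8, 5)).astype(float)
            p = rng.uniform(0.01, 0.99, (8, 5))
            params = FocalLossParams(gamma=0.0, epsilon=1e-7)
            assert focal_loss(y, p, params) == pytest.approx(
                bce(y, p, params.epsilon), abs=1e-10
            )

    def test_perfect_prediction_near_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert focal_loss(y, y, FocalLossParams(gamma=2.0)) < 1e-5

    def test_nonnegative_and_gamma2_below_gamma0(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            y = rng.integers(0, 2, (6, 4)).astype(float)
            p = rng.uniform(0.01, 0.99, (6, 4))
            l2 = focal_loss(y, p, FocalLossParams(gamma=2.0))
            l0 = focal_loss(y, p, FocalLossParams(gamma=0.0))
            assert 0.0 <= l2 <= l0  # modulation factor (1-p_correct)^2 <= 1

    def test_shape_mismatch_and_bad_probabilities_raise(self):
        with pytest.raises(ValueError, match="shape"):
            focal_loss(np.ones((2, 3)), np.ones((2, 2)) * 0.5)
        with pytest.raises(ValueError, match="probabilities"):
            focal_loss(np.ones((1, 2)), np.array([[0.5, 1.2]]))


def toy_dataset(n=120, L=3, p=6, seed=0):
    """Linearly separable multi-label data (each label = sign of one score)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    W = rng.normal(size=(p, L))
    Y = (X @ W > 0).astype(int)
    Y[Y.sum(1) == 0, 0] = 1
    return MultiLabelDataset(X=X, Y=Y)


class TestCSMLP:
    def test_recovers_planted_signal(self, recovery_run):
        """Held-out micro-F1 >= 0.90 when labels fully determine features."""
        assert recovery_run["report"].micro_f1 >= 0.90

    def test_deterministic_given_seed(self):
        D = toy_dataset()
        cfg = TrainConfig(epochs=5, hidden=(16,), seed=3)
        a = train_csmlp(D, cfg).predict_proba(D.X)
        b = train_csmlp(D, cfg).predict_proba(D.X)
        np.testing.assert_array_equal(a, b)

    def test_more_epochs_reach_higher_f1_via_checkpointing(self):
        from odorml.evaluation import micro_scores

        D = toy_dataset(n=200, seed=1)
        short = train_csmlp(D, TrainConfig(epochs=1, hidden=(32,), seed=0))
        long = train_csmlp(D, TrainConfig(epochs=25, hidden=(32,), seed=0))
        _, ps = short.predict(D.X)
        _, pl = long.predict(D.X)
        f_short = micro_scores(D.Y, ps)[2]
        f_long = micro_scores(D.Y, pl)[2]
        assert f_long >= f_short
        assert long.best_epoch >= short.best_epoch

    def test_zero_positive_label_warns(self):
        D = toy_dataset(n=60)
        D.Y[:, 2] = 0
        with pytest.warns(UserWarning, match="zero positives"):
            train_csmlp(
                D, TrainConfig(epochs=2, hidden=(8,), validation_fraction=0.0)
            )

    def test_probabilities_in_unit_interval(self):
        D = toy_dataset(n=80)
        m = train_csmlp(D, TrainConfig(epochs=3, hidden=(8,), seed=0))
        p = m.predict_proba(D.X)
        assert ((p >= 0) & (p <= 1)).all()
        assert p.shape == (80, D.n_labels)


class TestBinaryRelevance:
    def test_single_label_matches_bare_base_learner(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 6))
        y = (X[:, 0] > 0).astype(int)  # both classes present
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            D = MultiLabelDataset(X=X, Y=y[:, None])
        base = LogisticRegression(max_iter=1000)
        br = train_binary_relevance(D, base)
        bare = LogisticRegression(max_iter=1000).fit(D.X, D.Y[:, 0])
        np.testing.assert_allclose(
            br.predict_proba(D.X)[:, 0], bare.predict_proba(D.X)[:, 1]
        )

    def test_prediction_shape(self):
        D = toy_dataset(L=4, seed=3)
        br = train_binary_relevance(D)
        p, b = br.predict(D.X)
        assert p.shape == b.shape == (D.n_instances, 4)

    def test_zero_positive_label_constant_negative(self):
        D = toy_dataset(n=60, L=3)
        D.Y[:, 1] = 0
        with pytest.warns(UserWarning, match="constant"):
            br = train_binary_relevance(D)
        p, b = br.predict(D.X)
        assert (p[:, 1] == 0).all() and (b[:, 1] == 0).all()

    def test_memorizing_learner_perfect_training_f1(self):
        from odorml.evaluation import micro_scores

        D = toy_dataset(n=100, L=3, seed=4)
        br = train_binary_relevance(D, DecisionTreeClassifier(random_state=0))
        _, b = br.predict(D.X)
        assert micro_scores(D.Y, b)[2] == 1.0


class TestClassifierChain:
    def test_single_label_identical_to_br(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 4))
        y = (X[:, 1] + X[:, 2] > 0).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            D = MultiLabelDataset(X=X, Y=y[:, None])
        cc = train_classifier_chain(D)
        br = train_binary_relevance(D)
        np.testing.assert_allclose(
            cc.predict_proba(D.X)[:, 0], br.predict_proba(D.X)[:, 0]
        )

    def test_classifier_j_sees_p_plus_j_minus_1_features(self):
        D = toy_dataset(L=4, p=6, seed=6)
        cc = train_classifier_chain(D)
        for j, clf in enumerate(cc.classifiers_):
            assert clf.coef_.shape[1] == 6 + j

    def test_exploits_copied_label(self):
        """When label 2 is a copy of label 1, the chain can forward its
        label-1 call, so its label-2 accuracy is not worse than BR's."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 5))
        y1 = (X[:, 0] + 0.5 * rng.normal(size=300) > 0).astype(int)
        Y = np.column_stack([y1, y1])
        Y[Y.sum(1) == 0, 0] = 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            D = MultiLabelDataset(X=X, Y=Y)
        cc = train_classifier_chain(D)
        br = train_binary_relevance(D)
        _, pc = cc.predict(D.X)
        _, pb = br.predict(D.X)
        acc_cc = (pc[:, 1] == Y[:, 1]).mean()
        acc_br = (pb[:, 1] == Y[:, 1]).mean()
        assert acc_cc >= acc_br - 0.02

    def test_memorizing_learner_perfect_training_f1(self):
        from odorml.evaluation import micro_scores

        D = toy_dataset(n=100, L=3, seed=8)
        cc = train_classifier_chain(D, DecisionTreeClassifier(random_state=0))
        _, b = cc.predict(D.X)
        assert micro_scores(D.Y, b)[2] == 1.0


class TestRandomForestAndPredict:
    def test_rf_shapes_and_probabilities(self):
        D = toy_dataset(L=3, seed=9)
        rf = train_random_forest(D, n_estimators=30, seed=0)
        p, b = rf.predict(D.X)
        assert p.shape == (D.n_instances, 3)
        assert ((p >= 0) & (p <= 1)).all()

    @pytest.mark.parametrize("factory", [
        lambda D: train_binary_relevance(D),
        lambda D: train_random_forest(D, n_estimators=20, seed=0),
    ])
    def test_threshold_extremes_and_monotonicity(self, factory):
        D = toy_dataset(n=80, L=3, seed=10)
        model = factory(D)
        _, all_ones = predict(model, D.X, threshold=0.0)
        assert all_ones.all()
        _, all_zero = predict(model, D.X, threshold=1.0 + 1e-9)
        assert not all_zero.any()
        _, lo = predict(model, D.X, threshold=0.3)
        _, hi = predict(model, D.X, threshold=0.7)
        assert not (hi & ~lo).any()  # raising threshold never flips 0 -> 1
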