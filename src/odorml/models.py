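"""Multi-label classifiers behind one train/predict contract.

Four model families, all emitting per-label probabilities:

* **CSMLP** — a cost-sensitive multilayer perceptron: fully connected ReLU
  hidden layers with dropout, per-label sigmoid outputs, trained with the
  Adam optimizer on the *focal loss*, a cross-entropy variant that scales
  each term by ``(1 - p_correct)^gamma`` so well-classified (mostly
  majority-label) cells contribute little gradient and hard minority cells
  dominate.  Weights are checkpointed at the epoch with the best validation
  micro-F1.
* **Binary Relevance (BR)** — one independent binary classifier per label.
* **Classifier Chains (CC)** — like BR, but classifier *j*'s feature space
  is augmented with the 0/1 relevances of labels 1..j-1 (true labels while
  training, the chain's own predictions at inference), so label
  correlations can be exploited.
* **Random forest (RF)** — scikit-learn's native multi-output forest as the
  tree-ensemble baseline.

The focal loss implemented here is, per cell,
``-( (1-p)^g * y * log(p+eps) + p^g * (1-y) * log(1-p+eps) )``
summed over labels and averaged over instances; ``g = 0`` recovers plain
binary cross-entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone as sk_clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .datasets import MultiLabelDataset
from .resampling import iterative_split_indices

__all__ = [
    "FocalLossParams",
    "TrainConfig",
    "focal_loss",
    "focal_loss_grad",
    "CSMLPModel",
    "BinaryRelevanceModel",
    "ClassifierChainModel",
    "RandomForestModel",
    "train_csmlp",
    "train_binary_relevance",
    "train_classifier_chain",
    "train_random_forest",
    "predict",
]


@dataclass
class FocalLossParams:
    """gamma: focusing parameter (0 = plain BCE); epsilon: stability
    constant added inside the logs."""

    gamma: float = 2.0
    epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.epsilon < 1e-3):
            raise ValueError("epsilon must lie in (0, 1e-3)")


@dataclass
class TrainConfig:
    """CSMLP training hyper-parameters.

    hidden : sizes of the fully connected ReLU layers
    dropout : drop probability applied to each hidden layer while training
    validation_fraction : held-out share of the training set (iteratively
        stratified) used for best-epoch checkpointing by micro-F1
    threshold : probability cut for turning sigmoid outputs into 0/1 calls
    """

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout: float = 0.3
    hidden: tuple[int, ...] = (512, 256)
    threshold: float = 0.5
    seed: int = 0
    validation_fraction: float = 0.1
    checkpoint: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in [0, 1)")


def focal_loss(
    y_true: np.ndarray, y_pred: np.ndarray, params: FocalLossParams | None = None
) -> float:
    """Focal loss: sum over labels, mean over instances.

    ``y_pred`` must hold probabilities in [0, 1]; shapes must match.
    """
    params = params or FocalLossParams()
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"shape mismatch: y_true {y_true.shape} vs y_pred {y_pred.shape}"
        )
    if (y_pred < 0).any() or (y_pred > 1).any():
        raise ValueError("y_pred must hold probabilities in [0, 1]")
    y_true = np.atleast_2d(y_true)
    y_pred = np.atleast_2d(y_pred)
    g, eps = params.gamma, params.epsilon
    pos = (1.0 - y_pred) ** g * y_true * np.log(y_pred + eps)
    neg = y_pred**g * (1.0 - y_true) * np.log(1.0 - y_pred + eps)
    return float(-(pos + neg).sum(axis=1).mean())


def focal_loss_grad(
    y_true: np.ndarray, y_pred: np.ndarray, params: FocalLossParams
) -> np.ndarray:
    """d(focal loss)/d(y_pred), same shape as the inputs.

    Probabilities are clipped away from {0, 1} so the gamma < 1 powers stay
    finite; with gamma = 0 the modulation terms vanish identically.
    """
    g, eps = params.gamma, params.epsilon
    n = y_true.shape[0]
    p = np.clip(y_pred, 1e-7, 1.0 - 1e-7)
    y = y_true
    d_pos = (1.0 - p) ** g * y / (p + eps)
    d_neg = -(p**g) * (1.0 - y) / (1.0 - p + eps)
    if g > 0:
        d_pos = d_pos - g * (1.0 - p) ** (g - 1.0) * y * np.log(p + eps)
        d_neg = d_neg + g * p ** (g - 1.0) * (1.0 - y) * np.log(1.0 - p + eps)
    return -(d_pos + d_neg) / n


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _micro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = float(((y_true == 1) & (y_pred == 1)).sum())
    fp = float(((y_true == 0) & (y_pred == 1)).sum())
    fn = float(((y_true == 1) & (y_pred == 0)).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


class CSMLPModel:
    """Feed-forward net: ReLU hidden layers, sigmoid outputs, focal loss."""

    kind = "CSMLP"

    def __init__(
        self,
        n_features: int,
        n_labels: int,
        cfg: TrainConfig,
        loss: FocalLossParams,
    ) -> None:
        self.cfg = cfg
        self.loss = loss
        self.n_features = n_features
        self.n_labels = n_labels
        rng = np.random.default_rng(cfg.seed)
        sizes = [n_features, *cfg.hidden, n_labels]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.history: list[dict] = []
        self.best_epoch: int | None = None

    # -- forward ---------------------------------------------------------
    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray]]:
        """Returns (hidden activations incl. input, probabilities, masks)."""
        acts = [X]
        masks = []
        h = X
        drop = self.cfg.dropout
        for i in range(len(self.W) - 1):
            z = h @ self.W[i] + self.b[i]
            h = np.maximum(z, 0.0)
            if rng is not None and drop > 0:
                mask = (rng.random(h.shape) >= drop) / (1.0 - drop)
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        p = _sigmoid(h @ self.W[-1] + self.b[-1])
        return acts, p, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        _, p, _ = self._forward(X, rng=None)
        return p

    def predict(
        self, X: np.ndarray, threshold: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        thr = self.cfg.threshold if threshold is None else threshold
        p = self.predict_proba(X)
        return p, (p >= thr).astype(np.int8)

    # -- training --------------------------------------------------------
    def _adam_init(self) -> None:
        self._m = [np.zeros_like(w) for w in self.W + self.b]
        self._v = [np.zeros_like(w) for w in self.W + self.b]
        self._t = 0

    def _adam_step(self, grads: list[np.ndarray]) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.cfg.learning_rate
        self._t += 1
        params = self.W + self.b
        for k, (p, g) in enumerate(zip(params, grads)):
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1**self._t)
            vhat = self._v[k] / (1 - b2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def _backward(
        self,
        acts: list[np.ndarray],
        p: np.ndarray,
        masks: list[np.ndarray],
        y: np.ndarray,
    ) -> list[np.ndarray]:
        dL_dp = focal_loss_grad(y, p, self.loss)
        delta = dL_dp * p * (1.0 - p)  # chain through the sigmoid
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        return gW + gb

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        X_val: np.ndarray | None = None,
        Y_val: np.ndarray | None = None,
    ) -> "CSMLPModel":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if (Y.sum(axis=0) == 0).any():
            warnings.warn(
                "training labels with zero positives: those outputs will "
                "emit a near-constant probability",
                UserWarning,
                stacklevel=2,
            )
        rng = np.random.default_rng(self.cfg.seed + 1)
        self._adam_init()
        use_val = X_val is not None and len(X_val) > 0
        best_f1 = -1.0
        best_state = None
        n = X.shape[0]
        for epoch in range(self.cfg.epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start : start + self.cfg.batch_size]
                acts, p, masks = self._forward(X[idx], rng=rng)
                ep_loss += focal_loss(Y[idx], p, self.loss) * idx.size
                self._adam_step(self._backward(acts, p, masks, Y[idx]))
            Xc, Yc = (X_val, Y_val) if use_val else (X, Y)
            _, pred = self.predict(Xc)
            f1 = _micro_f1(np.asarray(Yc), pred)
            self.history.append(
                {"epoch": epoch, "train_loss": ep_loss / n, "val_micro_f1": f1}
            )
            if self.cfg.checkpoint and f1 >= best_f1:
                best_f1 = f1
                best_state = (
                    [w.copy() for w in self.W],
                    [b.copy() for b in self.b],
                )
                self.best_epoch = epoch
        if best_state is not None:
            self.W, self.b = best_state
        return self


def train_csmlp(
    train: MultiLabelDataset,
    cfg: TrainConfig | None = None,
    loss: FocalLossParams | None = None,
) -> CSMLPModel:
    """Train a cost-sensitive MLP on a multi-label dataset.

    A ``validation_fraction`` share of the training set is held out by
    iterative stratification; the returned model carries the weights from
    the epoch with the greatest validation micro-F1.  Deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    loss = loss or FocalLossParams()
    if train.n_instances < 2:
        raise ValueError("need at least two training instances")
    model = CSMLPModel(train.n_features, train.n_labels, cfg, loss)
    if cfg.validation_fraction > 0 and train.n_instances >= 20:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fit_idx, val_idx = iterative_split_indices(
                train.Y,
                fractions=(1 - cfg.validation_fraction, cfg.validation_fraction),
                seed=cfg.seed,
            )
        model.fit(
            train.X[fit_idx],
            train.Y[fit_idx],
            train.X[val_idx],
            train.Y[val_idx],
        )
    else:
        model.fit(train.X, train.Y)
    return model


class _ConstantLabel:
    """Stand-in classifier for a single-class training column."""

    def __init__(self, p: float) -> None:
        self.p = p

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.p)


def _fit_binary(base, X: np.ndarray, y: np.ndarray):
    """Fit a clone of ``base`` on one label column, handling constants."""
    classes = np.unique(y)
    if classes.size == 1:
        warnings.warn(
            "label column is constant in training data; emitting a "
            "constant classifier",
            UserWarning,
            stacklevel=3,
        )
        return _ConstantLabel(float(classes[0]))
    clf = sk_clone(base)
    clf.fit(X, y)
    return clf


def _proba_pos(clf, X: np.ndarray) -> np.ndarray:
    if isinstance(clf, _ConstantLabel):
        return clf.predict_proba_pos(X)
    proba = clf.predict_proba(X)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return proba[:, pos_col]


class BinaryRelevanceModel:
    """One independent binary classifier per label."""

    kind = "BR"

    def __init__(self, base_learner=None) -> None:
        self.base = base_learner if base_learner is not None else LogisticRegression(
            max_iter=1000
        )
        self.classifiers_: list = []
        self.n_labels: int | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "BinaryRelevanceModel":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        self.n_labels = Y.shape[1]
        self.classifiers_ = [
            _fit_binary(self.base, X, Y[:, j]) for j in range(self.n_labels)
        ]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([_proba_pos(c, X) for c in self.classifiers_])

    def predict(
        self, X: np.ndarray, threshold: float = 0.5
    ) -> tuple[np.ndarray, np.ndarray]:
        p = self.predict_proba(X)
        return p, (p >= threshold).astype(np.int8)


class ClassifierChainModel:
    """Chained binary classifiers exploiting label correlations.

    Classifier *j* is trained on the features augmented with the *true* 0/1
    relevances of the labels earlier in the chain; at prediction time the
    chain feeds its own thresholded outputs forward.
    """

    kind = "CC"

    def __init__(self, base_learner=None, order=None, seed: int = 0) -> None:
        self.base = base_learner if base_learner is not None else LogisticRegression(
            max_iter=1000
        )
        self.order = order
        self.seed = seed
        self.classifiers_: list = []
        self.order_: np.ndarray | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "ClassifierChainModel":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        L = Y.shape[1]
        if self.order is None:
            self.order_ = np.arange(L)
        elif isinstance(self.order, str) and self.order == "shuffle":
            self.order_ = np.random.default_rng(self.seed).permutation(L)
        else:
            self.order_ = np.asarray(self.order)
        self.classifiers_ = []
        aug = X
        for j in self.order_:
            self.classifiers_.append(_fit_binary(self.base, aug, Y[:, j]))
            aug = np.column_stack([aug, Y[:, j]])
        return self

    def predict_proba(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        L = self.order_.size
        proba = np.zeros((X.shape[0], L))
        aug = X
        for step, j in enumerate(self.order_):
            p = _proba_pos(self.classifiers_[step], aug)
            proba[:, j] = p
            aug = np.column_stack([aug, (p >= threshold).astype(float)])
        return proba

    def predict(
        self, X: np.ndarray, threshold: float = 0.5
    ) -> tuple[np.ndarray, np.ndarray]:
        p = self.predict_proba(X, threshold=threshold)
        return p, (p >= threshold).astype(np.int8)


class RandomForestModel:
    """scikit-learn multi-output random forest baseline."""

    kind = "RF"

    def __init__(self, n_estimators: int = 200, seed: int = 0, **kw) -> None:
        self.forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1, **kw
        )
        self.n_labels: int | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RandomForestModel":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        self.n_labels = Y.shape[1]
        self._constant = Y.min(axis=0) == Y.max(axis=0)
        self._constant_vals = Y[0].astype(float)
        if self._constant.any():
            warnings.warn(
                "constant label column(s) in training data", UserWarning,
                stacklevel=2,
            )
        self.forest.fit(X, Y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        raw = self.forest.predict_proba(X)
        out = np.zeros((X.shape[0], self.n_labels))
        for j in range(self.n_labels):
            if self._constant[j]:
                out[:, j] = self._constant_vals[j]
                continue
            classes = self.forest.classes_[j]
            pos = int(np.flatnonzero(classes == 1)[0])
            out[:, j] = raw[j][:, pos]
        return out

    def predict(
        self, X: np.ndarray, threshold: float = 0.5
    ) -> tuple[np.ndarray, np.ndarray]:
        p = self.predict_proba(X)
        return p, (p >= threshold).astype(np.int8)


def train_binary_relevance(
    train: MultiLabelDataset, base_learner=None
) -> BinaryRelevanceModel:
    """Fit Binary Relevance: one independent binary model per label."""
    return BinaryRelevanceModel(base_learner).fit(train.X, train.Y)


def train_classifier_chain(
    train: MultiLabelDataset, base_learner=None, order=None, seed: int = 0
) -> ClassifierChainModel:
    """Fit a Classifier Chain in the given (or dataset) label order."""
    return ClassifierChainModel(base_learner, order=order, seed=seed).fit(
        train.X, train.Y
    )


def train_random_forest(
    train: MultiLabelDataset, n_estimators: int = 200, seed: int = 0, **kw
) -> RandomForestModel:
    """Fit the multi-output random-forest baseline."""
    return RandomForestModel(n_estimators=n_estimators, seed=seed, **kw).fit(
        train.X, train.Y
    )


def predict(
    model, X: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, binary calls at ``threshold``) for any fitted model."""
    if hasattr(model, "predict_proba"):
        if model.kind == "CC":
            p = model.predict_proba(X, threshold=threshold)
        else:
            p = model.predict_proba(np.asarray(X, dtype=float))
        return p, (p >= threshold).astype(np.int8)
    raise TypeError(f"unsupported model: {model!r}")
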