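"""Shapley-value feature attribution for trained multi-label models.

The Shapley value of feature *i* for a prediction f(x) is the average, over
all feature orderings, of the change in model output when feature *i* is
revealed; "absent" features are imputed from rows of a background dataset.
This is the unique attribution satisfying linearity, symmetry, efficiency
(base value plus contributions reconstructs the prediction) and the
null-player axiom.  The cost of exact enumeration grows as 2^K, so for
K <= ``exact_max_features`` the value function is enumerated exactly and
above that a Monte-Carlo estimate over sampled feature orderings is used.

Per-label importance is aggregated the way odor-attribution studies report
it: features are ranked per label by mean |phi| over the evaluation
instances, the top-k per label are pooled, and each pooled feature gets a
weight proportional to how many labels selected it.
"""

from __future__ import annotations

from math import factorial

import numpy as np
import pandas as pd

from .featurize import SpectrumVector

__all__ = [
    "shapley_sampling",
    "shapley_values",
    "aggregate_top_features",
    "overlay_importance",
]


def _as_predict_fn(model):
    if callable(model) and not hasattr(model, "predict_proba"):
        return model
    return lambda X: np.atleast_2d(model.predict_proba(np.asarray(X, dtype=float)))


def _value_function(predict_fn, x, background):
    """f_x(S) evaluator: mean model output over background-imputed rows."""

    def v(mask: np.ndarray) -> np.ndarray:
        rows = background.copy()
        rows[:, mask] = x[mask]
        return predict_fn(rows).mean(axis=0)

    return v


def _exact_shapley(predict_fn, x, background):
    K = x.size
    v = _value_function(predict_fn, x, background)
    # value of every coalition, keyed by bitmask
    values = {}
    for code in range(1 << K):
        mask = np.array([(code >> i) & 1 for i in range(K)], dtype=bool)
        values[code] = v(mask)
    C = np.atleast_1d(values[0]).size
    phi = np.zeros((K, C))
    fact = [factorial(k) for k in range(K + 1)]
    for i in range(K):
        for code in range(1 << K):
            if (code >> i) & 1:
                continue
            s = bin(code).count("1")
            w = fact[s] * fact[K - s - 1] / fact[K]
            phi[i] += w * (values[code | (1 << i)] - values[code])
    phi0 = np.atleast_1d(predict_fn(background).mean(axis=0))
    return phi, phi0


def _sampled_shapley(predict_fn, x, background, n_permutations, rng):
    K = x.size
    B = background.shape[0]
    # cycle background rows so each is used near-equally
    bg_order = np.tile(rng.permutation(B), n_permutations // B + 1)
    probe = np.atleast_1d(predict_fn(x[None, :])[0])
    phi = np.zeros((K, probe.size))
    for t in range(n_permutations):
        order = rng.permutation(K)
        b = background[bg_order[t]]
        # progressive reveal: row j has features order[:j] taken from x
        rows = np.repeat(b[None, :], K + 1, axis=0)
        for j, feat in enumerate(order):
            rows[j + 1 :, feat] = x[feat]
        out = np.atleast_2d(predict_fn(rows))
        diffs = out[1:] - out[:-1]
        phi[order] += diffs
    phi /= n_permutations
    phi0 = np.atleast_1d(predict_fn(background).mean(axis=0))
    return phi, phi0


def shapley_sampling(
    model,
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
    exact_max_features: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Shapley attributions of one instance's prediction, per label.

    Parameters
    ----------
    model : fitted model with ``predict_proba`` or a plain callable
        mapping an (m, K) matrix to (m, C) outputs.
    x : feature vector of length K.
    background : (B, K) matrix used to impute absent features.
    n_permutations : Monte-Carlo sample size when K exceeds
        ``exact_max_features``; ignored under exact enumeration.
    seed : RNG seed; the estimate is deterministic given it.

    Returns
    -------
    phi : (K, C) contributions; phi0 : (C,) base values (mean model output
    over the background).  Under exact enumeration
    ``phi0 + phi.sum(0) == f(x)`` to numerical precision (efficiency);
    under sampling the identity holds up to Monte-Carlo error.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    if background.shape[1] != x.size:
        raise ValueError("background width must match the instance")
    predict_fn = _as_predict_fn(model)
    if x.size <= exact_max_features:
        return _exact_shapley(predict_fn, x, background)
    rng = np.random.default_rng(seed)
    return _sampled_shapley(predict_fn, x, background, n_permutations, rng)


def shapley_values(
    model,
    X_eval: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 50,
    seed: int = 0,
    exact_max_features: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Attributions for a batch of instances: (n, K, C) plus phi0 (C,)."""
    X_eval = np.atleast_2d(np.asarray(X_eval, dtype=float))
    phis = []
    phi0 = None
    for i, x in enumerate(X_eval):
        phi, phi0 = shapley_sampling(
            model,
            x,
            background,
            n_permutations=n_permutations,
            seed=seed + i,
            exact_max_features=exact_max_features,
        )
        phis.append(phi)
    return np.stack(phis), phi0


def aggregate_top_features(
    phi: np.ndarray, k: int = 20
) -> tuple[dict[int, np.ndarray], dict[int, float]]:
    """Per-label top-k features by mean |phi|, pooled with frequency weights.

    Parameters
    ----------
    phi : (n_instances, K, C) or (K, C) attribution array.
    k : number of features kept per label.

    Returns
    -------
    top_features : label index -> top-k feature indices, most important
        first.
    weights : feature index -> weight proportional to the number of labels
        whose top-k contains the feature, normalised to sum 1.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 2:
        phi = phi[None, :, :]
    if phi.ndim != 3:
        raise ValueError("phi must have shape (n, K, C) or (K, C)")
    importance = np.abs(phi).mean(axis=0)  # (K, C)
    K, C = importance.shape
    k_eff = min(k, K)
    top: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for c in range(C):
        order = np.argsort(-importance[:, c], kind="stable")[:k_eff]
        top[c] = order
        for f in order:
            counts[int(f)] = counts.get(int(f), 0) + 1
    total = sum(counts.values())
    weights = {f: counts[f] / total for f in sorted(counts)}
    return top, weights


def overlay_importance(
    weights: dict[int, float], mean_spectrum: SpectrumVector
) -> pd.DataFrame:
    """Overlay pooled feature weights onto an averaged spectrum.

    Emits one row per grid bin with (position, mean_intensity, weight);
    bins outside the weighted set carry weight 0.  Rendering (e.g. a
    red-to-blue ramp by decreasing weight) is left to the caller.
    """
    grid = np.asarray(mean_spectrum.grid, dtype=float)
    values = np.asarray(mean_spectrum.values, dtype=float)
    w = np.zeros(grid.size)
    for f, weight in weights.items():
        if not (0 <= f < grid.size):
            raise ValueError(
                f"feature index {f} outside the {grid.size}-bin grid"
            )
        w[f] = weight
    return pd.DataFrame(
        {"position": grid, "mean_intensity": values, "weight": w}
    )
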