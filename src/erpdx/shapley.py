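"""Interventional Shapley value attribution for tabular classifiers.

Attributes a model output f(x) to the input features with respect to a
background dataset B: the value of a coalition S is the mean of f over B
with the columns in S replaced by x's values, and a feature's Shapley
value is its average marginal contribution over coalitions.  The
per-row attributions satisfy additivity
``sum_i phi_i = f(x) - mean_B f`` along with the null-player and
symmetry axioms.

Two estimators:

- ``exact``: full subset enumeration, O(2^d) coalition evaluations —
  feasible for small feature counts (d <= ~15) and exact, so the game
  axioms hold to floating-point equality;
- ``permutation``: seeded Monte-Carlo over feature permutations; each
  permutation contributes one telescoping pass x -> background, so
  additivity holds exactly per permutation and the estimate converges
  to the exact value as the permutation count grows.

``method="auto"`` picks exact for d <= 12.
"""

from __future__ import annotations

from math import comb

import numpy as np

from erpdx.errors import ConfigError

EXACT_MAX_FEATURES = 12


def shapley_values(predict,
                   X,
                   background,
                   method: str = "auto",
                   n_permutations: int = 16,
                   seed: int = 0) -> tuple[np.ndarray, float]:
    """Shapley attributions of ``predict`` for each row of ``X``.

    Parameters
    ----------
    predict : callable
        Maps an (n, d) array to an (n,) array of model outputs
        (typically the positive-class probability).
    X : (m, d) array
        Rows to explain.
    background : (b, d) array
        Reference dataset defining the "feature absent" distribution.
    method : {"auto", "exact", "permutation"}
    n_permutations : int
        Permutations per explained row (permutation estimator).
    seed : int
        Seed for the permutation draws.

    Returns
    -------
    phi : (m, d) array of signed attributions.
    base_value : float, mean model output over the background.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if X.ndim != 2 or background.ndim != 2 or X.shape[1] != background.shape[1]:
        raise ConfigError("X and background must be 2-D with equal feature counts")
    d = X.shape[1]
    if method == "auto":
        method = "exact" if d <= EXACT_MAX_FEATURES else "permutation"
    base_value = float(np.mean(predict(background)))

    if method == "exact":
        phi = _exact(predict, X, background)
    elif method == "permutation":
        phi = _permutation(predict, X, background, n_permutations, seed)
    else:
        raise ConfigError(f"unknown method {method!r}")
    return phi, base_value


def _coalition_value(predict, x: np.ndarray, background: np.ndarray,
                     mask: np.ndarray) -> float:
    z = background.copy()
    z[:, mask] = x[mask]
    return float(np.mean(predict(z)))


def _exact(predict, X, background) -> np.ndarray:
    d = X.shape[1]
    if d > 20:
        raise ConfigError(f"exact estimator infeasible for d={d}")
    n_subsets = 1 << d
    # Shapley kernel weights |S|!(d-|S|-1)!/d! depend only on |S|
    w = np.array([1.0 / (d * comb(d - 1, s)) for s in range(d)])

    phi = np.zeros((X.shape[0], d))
    for r, x in enumerate(X):
        v = np.empty(n_subsets)
        for m in range(n_subsets):
            mask = np.array([(m >> i) & 1 for i in range(d)], dtype=bool)
            v[m] = _coalition_value(predict, x, background, mask)
        for i in range(d):
            bit = 1 << i
            total = 0.0
            for m in range(n_subsets):
                if m & bit:
                    continue
                s = bin(m).count("1")
                total += w[s] * (v[m | bit] - v[m])
            phi[r, i] = total
    return phi


def _permutation(predict, X, background, n_permutations: int, seed: int) -> np.ndarray:
    d = X.shape[1]
    b = background.shape[0]
    rng = np.random.default_rng(seed)
    phi = np.zeros((X.shape[0], d))
    for r, x in enumerate(X):
        acc = np.zeros(d)
        batched = (d + 1) * b * d <= 20_000_000  # keep the stage tensor under ~160 MB
        for _ in range(n_permutations):
            order = rng.permutation(d)
            # telescoping pass: insert x's features one at a time
            z = background.copy()
            if batched:
                stages = np.empty((d + 1, b, d))
                stages[0] = z
                for k, i in enumerate(order):
                    z[:, i] = x[i]
                    stages[k + 1] = z
                means = predict(stages.reshape(-1, d)).reshape(d + 1, b).mean(axis=1)
            else:
                means = np.empty(d + 1)
                means[0] = np.mean(predict(z))
                for k, i in enumerate(order):
                    z[:, i] = x[i]
                    means[k + 1] = np.mean(predict(z))
            contrib = np.diff(means)  # contribution of order[k] at step k
            acc[order] += contrib
        phi[r] = acc / n_permutations
    return phi


def mean_abs_attribution(phi: np.ndarray) -> np.ndarray:
    """Global importance: mean |attribution| per feature over explained rows."""
    return np.abs(phi).mean(axis=0)
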