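"""Model-agnostic Shapley feature attributions.

Interventional value function: v(S) is the model's mean prediction with the
features in S taken from the explained instance and the rest marginalised
over a background sample.  Up to ``max_exact`` features the Shapley values
are computed exactly by subset enumeration (so local accuracy
``base + sum(phi) = prediction`` holds to numerical precision); beyond that
a seeded permutation-sampling estimator is used.
"""

from __future__ import annotations

from math import factorial

import numpy as np

__all__ = ["shapley_attributions", "mean_abs_importance"]


def _exact(predict_fn, background: np.ndarray, X: np.ndarray):
    n_bg, m = background.shape
    n_inst = X.shape[0]
    masks = np.array([[bool(s >> i & 1) for i in range(m)]
                      for s in range(2 ** m)])
    # v[instance, subset]
    v = np.empty((n_inst, 2 ** m))
    for s in range(2 ** m):
        mask = masks[s]
        batch = np.repeat(background[None, :, :], n_inst, axis=0)
        batch[:, :, mask] = X[:, None, mask]
        preds = predict_fn(batch.reshape(-1, m)).reshape(n_inst, n_bg)
        v[:, s] = preds.mean(axis=1)
    w = np.array([factorial(k) * factorial(m - k - 1) / factorial(m)
                  for k in range(m)])
    phi = np.zeros((n_inst, m))
    sizes = masks.sum(axis=1)
    for i in range(m):
        without = np.flatnonzero(~masks[:, i])
        with_i = without | (1 << i)
        phi[:, i] = np.sum((v[:, with_i] - v[:, without])
                           * w[sizes[without]], axis=1)
    base = v[:, 0]
    return phi, float(base[0])


def _sampled(predict_fn, background: np.ndarray, X: np.ndarray,
             n_perm: int, seed: int):
    rng = np.random.default_rng(seed)
    n_bg, m = background.shape
    n_inst = X.shape[0]
    phi = np.zeros((n_inst, m))
    base = float(np.mean(predict_fn(background)))
    for _ in range(n_perm):
        perm = rng.permutation(m)
        b = background[rng.integers(0, n_bg)]
        cur = np.repeat(b[None, :], n_inst, axis=0)
        prev = predict_fn(cur)
        for j in perm:
            cur[:, j] = X[:, j]
            nxt = predict_fn(cur)
            phi[:, j] += nxt - prev
            prev = nxt
    return phi / n_perm, base


def shapley_attributions(model, background, X, max_exact: int = 12,
                         n_perm: int = 200, seed: int = 0):
    """Per-instance, per-feature Shapley values plus the base value.

    ``model`` is anything with ``predict``; ``background`` the reference
    sample defining the marginal distribution; ``X`` the instances to
    explain.  Returns ``(phi, base)`` with ``phi`` of shape
    (n_instances, n_features).
    """
    background = np.asarray(background, dtype=float)
    X = np.asarray(X, dtype=float)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D array")
    if X.shape[1] != background.shape[1]:
        raise ValueError("instances and background disagree on the number "
                         "of features")
    predict_fn = model.predict if hasattr(model, "predict") else model
    if background.shape[1] <= max_exact:
        return _exact(predict_fn, background, X)
    return _sampled(predict_fn, background, X, n_perm, seed)


def mean_abs_importance(phi: np.ndarray) -> np.ndarray:
    """Global feature importance: mean absolute attribution per feature."""
    return np.mean(np.abs(phi), axis=0)
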