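"""Temporal weighting function and weighted average evidence.

The weight the averaging diffusion model places on the i-th of s_t presented
items is

    w_{s_t,i} = [1 - (1 - eps_primacy**i) * (1 - eps_recency**(s_t - i + 1))]
                * (1 - eta) + eta

with a small floor eta (0.01 by default).  eps_primacy inflates weights on
early items, eps_recency on late items; with both at zero all weights sit at
the floor, and eps_recency = 1 gives uniform weights (the unbiased average).
The model's decision variable is the weight-normalised mean of the IE shown
so far.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DEFAULT_ETA",
    "temporal_weight",
    "temporal_weight_matrix",
    "temporal_weight_matrix_batch",
    "weighted_ae",
    "recursive_ae_update",
    "observation_sd",
]

DEFAULT_ETA = 0.01


def temporal_weight(i, s_t: int, eps_primacy: float, eps_recency: float,
                    eta: float = DEFAULT_ETA):
    """Weight on item(s) ``i`` (1-based) after ``s_t`` items were shown."""
    i = np.asarray(i)
    if np.any(i < 1) or np.any(i > s_t):
        raise ValueError(f"item index must satisfy 1 <= i <= s_t={s_t}")
    w = (1.0 - (1.0 - eps_primacy ** i)
         * (1.0 - eps_recency ** (s_t - i + 1))) * (1.0 - eta) + eta
    return w[()] if w.ndim == 0 else w


def temporal_weight_matrix(n: int, eps_primacy: float, eps_recency: float,
                           eta: float = DEFAULT_ETA) -> np.ndarray:
    """Lower-triangular matrix W with W[s-1, i-1] = w_{s,i} for s, i in 1..n."""
    i = np.arange(1, n + 1)
    s = i[:, None]
    with np.errstate(invalid="ignore"):
        w = (1.0 - (1.0 - eps_primacy ** i[None, :])
             * (1.0 - eps_recency ** (s - i[None, :] + 1))) * (1.0 - eta) + eta
    return np.tril(w)


def temporal_weight_matrix_batch(n: int, eps_primacy, eps_recency,
                                 eta: float = DEFAULT_ETA) -> np.ndarray:
    """Stack of weight matrices for vectors of parameter values.

    Returns shape (m, n, n) with element [j, s-1, i-1] = w_{s,i} under the
    j-th parameter pair.  Used to evaluate the likelihood for a whole
    ensemble of walkers at once.
    """
    eps_p = np.atleast_1d(np.asarray(eps_primacy, dtype=float))
    eps_r = np.atleast_1d(np.asarray(eps_recency, dtype=float))
    k = np.arange(1, n + 1)
    pp = eps_p[:, None] ** k  # (m, n): eps_p^i
    rp = eps_r[:, None] ** k  # (m, n): eps_r^k
    K = k[:, None] - k[None, :]  # s - i, lower triangle >= 0
    w = (1.0 - (1.0 - pp[:, None, :])
         * (1.0 - rp[:, K.clip(min=0)])) * (1.0 - eta) + eta
    return np.where(K[None] >= 0, w, 0.0)


def weighted_ae(ie, eps_primacy: float, eps_recency: float,
                eta: float = DEFAULT_ETA) -> float:
    """Weighted average of the evidence shown so far (the model's mu)."""
    ie = np.asarray(ie, dtype=float)
    if ie.size == 0:
        raise ValueError("weighted_ae requires at least one evidence value")
    w = temporal_weight(np.arange(1, ie.size + 1), ie.size,
                        eps_primacy, eps_recency, eta)
    return float(np.dot(w, ie) / np.sum(w))


def recursive_ae_update(prev_ae, new_ie: float, fixed_weights) -> float:
    """Update a maintained AE estimate with one new item.

    Valid when the weight on each item does not change as s_t grows
    (w_{s,i} = w_i for all s); then

        AE(s) = (sum_{i<s} w_i / sum_{i<=s} w_i) AE(s-1)
              + (w_s / sum_{i<=s} w_i) IE_s

    reproduces the batch weighted average at every step.

    Parameters
    ----------
    prev_ae : float or None
        AE after the previous item; None (or with an empty weight history)
        means no item has been integrated yet.
    new_ie : float
        The newly presented evidence value.
    fixed_weights : array-like
        Time-invariant weights w_1..w_s including the new item's weight w_s.
    """
    w = np.asarray(fixed_weights, dtype=float)
    if w.size == 0:
        raise ValueError("fixed_weights must include the new item's weight")
    total = w.sum()
    if total <= 0:
        raise ValueError("weight sum must be positive")
    if prev_ae is None or w.size == 1:
        return float(new_ie)
    return float((total - w[-1]) / total * prev_ae + w[-1] / total * new_ie)


def observation_sd(t, sigma_w: float):
    """Standard deviation of the reported average at elapsed time ``t``.

    sigma(t) = sigma_w / sqrt(t): the report grows more precise as evidence
    accrues.  ``t`` is the time since trial onset in seconds.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    if sigma_w <= 0:
        raise ValueError("sigma_w must be > 0")
    out = sigma_w / np.sqrt(t)
    return out[()] if out.ndim == 0 else out
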