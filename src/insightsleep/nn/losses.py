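"""Masked, class-weighted negative log-likelihood over per-epoch logits."""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    return logits - logsumexp(logits, axis=axis, keepdims=True)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.exp(log_softmax(logits, axis=axis))


def masked_weighted_nll(
    log_probs: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Weighted mean of per-epoch -log p[y] over masked-in epochs.

    loss = sum_e w[y_e] * (-log p_e[y_e]) / sum_e w[y_e]; padded epochs
    (mask False) contribute nothing to either sum.
    """
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    if not mask.any():
        raise ValueError("no masked-in epochs to compute a loss over")
    idx = np.flatnonzero(mask)
    y = labels[idx]
    if (y < 0).any() or (y >= log_probs.shape[1]).any():
        raise ValueError("masked-in epoch carries an out-of-range label")
    w = weights[y]
    nll = -log_probs[idx, y]
    return float((w * nll).sum() / w.sum())


def masked_weighted_nll_with_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    weights: np.ndarray,
):
    """Loss value plus d(loss)/d(logits); zero rows for masked-out epochs."""
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    logp = log_softmax(logits)
    loss = masked_weighted_nll(logp, labels, mask, weights)
    idx = np.flatnonzero(mask)
    y = labels[idx]
    w = weights[y]
    p = np.exp(logp[idx])
    g = p * w[:, None]
    g[np.arange(len(idx)), y] -= w
    dlogits = np.zeros_like(logits)
    dlogits[idx] = g / w.sum()
    return loss, dlogits
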