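"""Class-weighted cross-entropy loss."""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

PROB_EPS = 1e-12


def weighted_cross_entropy(
    pred_probs: np.ndarray, targets: np.ndarray, weights: np.ndarray
) -> float:
    """-(1/N) * sum_n sum_i w_i * T_ni * ln(Y_ni).

    ``pred_probs`` rows must lie on the probability simplex; ``targets`` is
    one-hot.  Zero predicted probability at a true class is clamped at 1e-12
    and logged.
    """
    y = np.asarray(pred_probs, dtype=float)
    t = np.asarray(targets, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape != t.shape:
        raise ValueError("pred_probs and targets must have identical shape")
    if y.ndim != 2 or w.shape != (y.shape[1],):
        raise ValueError("expected N x K probabilities and K weights")
    if not np.allclose(y.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("pred_probs rows must sum to 1")
    hit_clamp = np.any((t > 0) & (y < PROB_EPS))
    if hit_clamp:
        log.warning("weighted_cross_entropy: zero probability at a true class clamped")
    n = y.shape[0]
    return float(-np.sum(w[None, :] * t * np.log(np.clip(y, PROB_EPS, None))) / n)
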