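"""Softmax and class-weighted categorical cross-entropy."""

from __future__ import annotations

import numpy as np


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weights: np.ndarray | None = None
):
    """Mean (optionally per-sample-weighted) cross-entropy and its logit gradient.

    Returns ``(loss, dlogits)`` with ``dlogits`` already divided by the
    batch size, ready to backpropagate.
    """
    n = logits.shape[0]
    p = softmax(logits)
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    if sample_weights is None:
        sample_weights = np.ones(n)
    loss = float(-(sample_weights * logp).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= sample_weights[:, None] / n
    return loss, dlogits
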