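"""Losses: softmax cross-entropy (classification) and MSE (regression).

Each returns ``(loss, grad_wrt_logits)`` with the gradient already averaged
over the batch.
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax_cross_entropy", "mse_loss", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    pred = pred.reshape(-1)
    target = np.asarray(target, dtype=np.float64).reshape(-1)
    diff = pred.astype(np.float64) - target
    loss = float(np.mean(diff**2))
    grad = (2.0 * diff / diff.size).astype(np.float32).reshape(-1, 1)
    return loss, grad
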