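"""Minimal numpy training utilities (Adam, softmax cross-entropy, batching).

The two trainable components of the pipeline — the dense reduction layer and
the attention-gated MLP — are small enough that closed-form gradients plus
Adam on the CPU train them in seconds; no autodiff framework is needed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logsumexp

__all__ = ["Adam", "softmax", "sigmoid", "cross_entropy", "iterate_minibatches", "train_val_split"]

sigmoid = expit


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for numerical stability."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean softmax cross-entropy; ``y`` holds integer class indices."""
    lse = logsumexp(logits, axis=1)
    return float(np.mean(lse - logits[np.arange(len(y)), y]))


class Adam:
    """Adaptive-moment gradient descent over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def iterate_minibatches(n: int, batch: int, rng: np.random.Generator):
    """Yield shuffled index batches covering all ``n`` samples once."""
    order = rng.permutation(n)
    for start in range(0, n, batch):
        yield order[start : start + batch]


def train_val_split(n: int, val_fraction: float, rng: np.random.Generator):
    """Deterministic shuffled train/validation index split."""
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if val_fraction > 0 else 0
    return order[n_val:], order[:n_val]
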