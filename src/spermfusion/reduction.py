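"""Trainable dense reduction of penultimate features (e.g. 1280 -> 128, ReLU).

High-dimensional backbone embeddings are projected into a compact latent
space by a single fully connected layer with a rectifier activation.  The
layer is trained post hoc on frozen extracted features: a temporary linear
softmax head is attached, the pair is optimized by cross-entropy with early
stopping on a held-out split, and the head is then discarded — only the
reduction layer is returned.  The same rectified map is applied at inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, cross_entropy, iterate_minibatches, softmax, train_val_split
from .containers import FeatureMatrix

__all__ = ["ReductionLayer", "ReductionTrainConfig", "fit_reduction", "apply_reduction"]


@dataclass
class ReductionLayer:
    """Affine map + rectifier: ``z = max(0, W x + b)`` with W of shape (out, in)."""

    weight: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weight.ndim != 2 or self.bias.shape != (self.weight.shape[0],):
            raise ValueError("weight must be (out, in) with matching bias")

    @property
    def in_dim(self) -> int:
        return self.weight.shape[1]

    @property
    def out_dim(self) -> int:
        return self.weight.shape[0]


@dataclass
class ReductionTrainConfig:
    """Training knobs for the reduction layer (batched Adam, early stopping)."""

    batch_size: int = 64
    max_epochs: int = 200
    learning_rate: float = 1e-3
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0


def fit_reduction(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    out_dim: int = 128,
    config: ReductionTrainConfig | None = None,
) -> ReductionLayer:
    """Train the rectified reduction layer with a temporary softmax head.

    The head (a linear classifier over the reduced features) exists only to
    give the layer a supervised objective; it is dropped after training.
    """
    config = config or ReductionTrainConfig()
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train the reduction layer")
    n, d = X.shape
    if out_dim >= d:
        raise ValueError("out_dim must be smaller than the input dimension")
    c = len(classes)
    rng = np.random.default_rng(config.seed)
    lim_w = np.sqrt(6.0 / (d + out_dim))
    lim_v = np.sqrt(6.0 / (out_dim + c))
    W = rng.uniform(-lim_w, lim_w, size=(out_dim, d))
    b = np.zeros(out_dim)
    V = rng.uniform(-lim_v, lim_v, size=(c, out_dim))
    vb = np.zeros(c)
    opt = Adam([W, b, V, vb], lr=config.learning_rate)
    tr, va = train_val_split(n, config.val_fraction, rng)
    if len(va) == 0 or len(tr) == 0:
        tr, va = np.arange(n), np.arange(n)

    def forward(idx):
        z = np.maximum(0.0, X[idx] @ W.T + b)
        return z, z @ V.T + vb

    best = (np.inf, None)
    since_best = 0
    for _ in range(config.max_epochs):
        for batch in iterate_minibatches(len(tr), config.batch_size, rng):
            idx = tr[batch]
            z, logits = forward(idx)
            p = softmax(logits)
            p[np.arange(len(idx)), y[idx]] -= 1.0
            p /= len(idx)
            gV = p.T @ z
            gvb = p.sum(axis=0)
            dz = (p @ V) * (z > 0)
            gW = dz.T @ X[idx]
            gb = dz.sum(axis=0)
            opt.step([gW, gb, gV, gvb])
        _, logits_va = forward(va)
        loss = cross_entropy(logits_va, y[va])
        if not np.isfinite(loss):
            raise RuntimeError("reduction training diverged (non-finite loss)")
        if loss < best[0] - 1e-6:
            best = (loss, (W.copy(), b.copy()))
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    W_best, b_best = best[1] if best[1] is not None else (W, b)
    return ReductionLayer(W_best, b_best)


def apply_reduction(
    layer: ReductionLayer, features: FeatureMatrix | np.ndarray
) -> FeatureMatrix | np.ndarray:
    """Apply ``max(0, W f + b)`` row-wise; preserves sample count and order."""
    if isinstance(features, FeatureMatrix):
        if features.dim != layer.in_dim:
            raise ValueError(
                f"feature dim {features.dim} does not match layer in_dim {layer.in_dim}"
            )
        reduced = np.maximum(0.0, features.values @ layer.weight.T + layer.bias)
        return FeatureMatrix(
            reduced, list(features.sample_ids), source_id=f"{features.source_id}_r{layer.out_dim}"
        )
    X = np.asarray(features, dtype=np.float64)
    if X.shape[1] != layer.in_dim:
        raise ValueError(f"feature dim {X.shape[1]} does not match layer in_dim {layer.in_dim}")
    return np.maximum(0.0, X @ layer.weight.T + layer.bias)
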