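"""Backbone adapters: penultimate-layer feature extraction behind one contract.

A *backbone* maps an image stack to ``(penultimate features n x D, logits
n x C)``; deep features taken from the penultimate (second-to-last) fully
connected layer serve as the embedding fed to fusion and to the classical
classifiers.  Two adapters are provided:

* :class:`TinyCnn` — a fixed-weight 2-conv-block reference network with a
  configurable penultimate width, used throughout the test suite (no GPU, no
  download, deterministic given its seed);
* :class:`EfficientNetV2Backbone` — an optional heavyweight plugin wrapping
  torchvision's EfficientNetV2 S/M/L (penultimate width 1280); it requires
  torch to be installed and is never needed by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from PIL import Image

from .containers import FeatureMatrix

__all__ = [
    "Backbone",
    "TinyCnn",
    "EfficientNetV2Backbone",
    "make_backbone",
    "extract_penultimate",
    "read_image_tree",
]


@runtime_checkable
class Backbone(Protocol):
    """Forward contract: image stack -> (penultimate features, class logits)."""

    id: str
    penultimate_dim: int

    def forward(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ...


def _to_float_gray(images: np.ndarray) -> np.ndarray:
    """(n, H, W, 3) uint8/float -> (n, H, W) float in [0, 1]."""
    x = np.asarray(images, dtype=np.float64)
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError("expected an image stack of shape (n, H, W, 3)")
    if x.max() > 1.5:
        x = x / 255.0
    return x.mean(axis=-1)


def _conv_valid(x: np.ndarray, kernels: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid 3x3 convolution.  x: (n,h,w,cin), kernels: (cout,cin,3,3)."""
    win = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(1, 2))
    # win: (n, h-2, w-2, cin, 3, 3)
    return np.einsum("nxycij,kcij->nxyk", win, kernels, optimize=True) + bias


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, : 2 * h2, : 2 * w2].reshape(n, h2, 2, w2, 2, c).mean(axis=(2, 4))


@dataclass
class TinyCnn:
    """Fixed-weight reference backbone: 2 conv blocks + pooling + FC penultimate.

    Weights are drawn once (He-scaled, seeded) and frozen; the network is a
    deterministic feature extractor, adequate for exercising every downstream
    stage without any training loop.
    """

    penultimate_dim: int = 16
    n_classes: int = 6
    input_side: int = 32
    seed: int = 0
    id: str = "tinycnn"
    _weights: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.input_side < 8:
            raise ValueError("input_side must be >= 8")
        rng = np.random.default_rng(self.seed)
        c1, c2 = 8, 16
        side = self.input_side
        h = (side - 2) // 2          # after conv1 + pool
        h = (h - 2) // 2             # after conv2 + pool
        flat = h * h * c2
        he = lambda fan_in, *shape: rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        self._weights = {
            "k1": he(9, c1, 1, 3, 3),
            "b1": np.zeros(c1),
            "k2": he(9 * c1, c2, c1, 3, 3),
            "b2": np.zeros(c2),
            "w_fc": he(flat, self.penultimate_dim, flat),
            "b_fc": np.zeros(self.penultimate_dim),
            "w_head": he(self.penultimate_dim, self.n_classes, self.penultimate_dim),
            "b_head": np.zeros(self.n_classes),
        }

    @property
    def head_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Classification-head parameters (for the features/logits consistency
        contract: ``logits == features @ W.T + b``)."""
        return self._weights["w_head"], self._weights["b_head"]

    def _resize(self, gray: np.ndarray) -> np.ndarray:
        if gray.shape[1] == gray.shape[2] == self.input_side:
            return gray
        from skimage.transform import resize

        return np.stack(
            [
                resize(g, (self.input_side, self.input_side), anti_aliasing=True)
                for g in gray
            ]
        )

    def forward(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = self._weights
        gray = self._resize(_to_float_gray(images))[..., None]
        h = np.maximum(0.0, _conv_valid(gray, w["k1"], w["b1"]))
        h = _avgpool2(h)
        h = np.maximum(0.0, _conv_valid(h, w["k2"], w["b2"]))
        h = _avgpool2(h)
        flat = h.reshape(h.shape[0], -1)
        feats = np.maximum(0.0, flat @ w["w_fc"].T + w["b_fc"])
        logits = feats @ w["w_head"].T + w["b_head"]
        return feats, logits


_EFFNET_VARIANTS = {"v2s": "efficientnet_v2_s", "v2m": "efficientnet_v2_m", "v2l": "efficientnet_v2_l"}


@dataclass
class EfficientNetV2Backbone:
    """EfficientNetV2 S/M/L adapter (penultimate width 1280).

    A thin wrapper over torchvision; all three variants expose a
    1280-dimensional penultimate embedding.  torch/torchvision must be
    installed, otherwise :meth:`forward` raises.  Training-time metadata
    (optimizer, learning rate) may be attached but is never interpreted here.
    """

    variant: str = "v2s"
    weights_path: str | None = None
    metadata: dict = field(default_factory=dict)
    penultimate_dim: int = 1280

    def __post_init__(self) -> None:
        if self.variant not in _EFFNET_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {sorted(_EFFNET_VARIANTS)}")
        self.id = self.variant

    def forward(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        try:
            import torch
            import torchvision
        except ImportError as exc:  # pragma: no cover - torch-optional plugin
            raise RuntimeError(
                "EfficientNetV2 adapters require torch and torchvision; "
                "use the TinyCnn reference backbone for CPU-only workflows"
            ) from exc
        ctor = getattr(torchvision.models, _EFFNET_VARIANTS[self.variant])
        model = ctor()
        if self.weights_path:
            model.load_state_dict(torch.load(self.weights_path, map_location="cpu"))
        model.eval()
        x = np.asarray(images, dtype=np.float32)
        if x.max() > 1.5:
            x = x / 255.0
        with torch.no_grad():
            t = torch.from_numpy(x).permute(0, 3, 1, 2)
            feats = model.avgpool(model.features(t)).flatten(1)
            logits = model.classifier(feats)
        return feats.numpy().astype(np.float64), logits.numpy().astype(np.float64)


def make_backbone(backbone_id: str, **kwargs) -> Backbone:
    """Resolve a backbone id (``tinycnn`` or ``v2s``/``v2m``/``v2l``)."""
    if backbone_id == "tinycnn":
        return TinyCnn(**kwargs)
    if backbone_id in _EFFNET_VARIANTS:
        return EfficientNetV2Backbone(variant=backbone_id, **kwargs)
    raise ValueError(f"unknown backbone id {backbone_id!r}")


def extract_penultimate(
    model: Backbone, images: np.ndarray, sample_ids: list[str] | None = None
) -> FeatureMatrix:
    """Run the backbone in inference mode and wrap its penultimate features.

    Deterministic given fixed model weights and inputs; raises on an empty
    stack or a channel mismatch.
    """
    images = np.asarray(images)
    if images.size == 0 or images.shape[0] == 0:
        raise ValueError("empty image stack")
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError("expected an image stack of shape (n, H, W, 3)")
    feats, _ = model.forward(images)
    if feats.shape != (images.shape[0], model.penultimate_dim):
        raise RuntimeError("backbone returned features of unexpected shape")
    return FeatureMatrix(feats, list(sample_ids or []), source_id=model.id)


def read_image_tree(root: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a class-per-subdirectory PNG/JPEG tree (the public dataset layout).

    Classes are the subdirectory names in alphabetical order; all images are
    returned as one uint8 stack (they must share a common size — adapters
    handle resizing to each backbone's input side).
    """
    root = Path(root)
    classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not classes:
        raise ValueError(f"{root}: no class subdirectories found")
    images, labels = [], []
    for cls in classes:
        for f in sorted((root / cls).iterdir()):
            if f.suffix.lower() in {".png", ".jpg", ".jpeg"}:
                images.append(np.asarray(Image.open(f).convert("RGB"), dtype=np.uint8))
                labels.append(cls)
    if not images:
        raise ValueError(f"{root}: no images found")
    return np.stack(images), np.asarray(labels, dtype=object)
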