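"""Synthetic fixtures with the statistical structure the pipeline assumes.

Real inputs to the pipeline are microscopy image crops of single sperm cells,
labelled with one of 18 morphology classes under severe imbalance, from which
several CNN backbones each produce an embedding ("view") per sample.  This
module emulates exactly that structure offline:

* :func:`generate_synthetic_features` — multiple correlated Gaussian feature
  views per sample with tunable class separability and an arbitrary
  (imbalanced) class-proportion profile;
* :func:`generate_synthetic_images` — parametric sperm-like glyphs (ellipse
  head + curved tail) whose shape parameters are class-determined;
* :func:`simulate_correlated_sources` — per-classifier probability matrices
  with controllable individual accuracy and pairwise error correlation, for
  studying soft-voting behaviour.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .classtable import ClassTable, HI_LAB_CLASS_COUNTS, make_class_table
from .containers import ClassProbabilityMatrix, FeatureMatrix, default_sample_ids

__all__ = [
    "SyntheticSpec",
    "apportion_counts",
    "generate_synthetic_features",
    "generate_synthetic_images",
    "simulate_correlated_sources",
    "hi_lab_proportions",
    "GLYPH_PARAMS",
]


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic multi-view dataset.

    Parameters
    ----------
    n_classes
        Number of classes.
    views
        ``(view_id, dimension)`` pairs, one per backbone view.
    separation
        Distance between class centroids in units of the (unit) noise s.d.
        0 means no class signal at all; 8 is near-perfectly separable.
    view_correlation
        Fraction (0–1) of the class signal that is shared across views; at 1
        equal-dimension views carry identical centroids, at 0 each view has an
        independent class geometry.
    class_proportions
        Simplex vector of per-class shares (sums to 1).
    n_samples
        Total number of samples; per-class counts are apportioned
        deterministically (largest remainder), never sampled.
    seed
        Master seed; identical specs produce bitwise-identical outputs.
    """

    n_classes: int
    views: tuple[tuple[str, int], ...]
    separation: float
    view_correlation: float
    class_proportions: np.ndarray
    n_samples: int
    seed: int
    class_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        self.views = tuple((str(v), int(d)) for v, d in self.views)
        if len(self.views) == 0:
            raise ValueError("at least one view is required")
        if any(d < 1 for _, d in self.views):
            raise ValueError("every view dimension must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if not 0.0 <= self.view_correlation <= 1.0:
            raise ValueError("view_correlation must lie in [0, 1]")
        p = np.asarray(self.class_proportions, dtype=np.float64)
        if p.shape != (self.n_classes,):
            raise ValueError("class_proportions length must equal n_classes")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1 (within 1e-9)")
        if np.any(p < 0):
            raise ValueError("class_proportions must be nonnegative")
        self.class_proportions = p
        if self.n_samples < self.n_classes:
            raise ValueError("n_samples must be >= n_classes")
        if self.class_names is not None:
            if len(self.class_names) != self.n_classes:
                raise ValueError("class_names length must equal n_classes")
            self.class_names = tuple(self.class_names)

    def resolved_class_names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            return self.class_names
        # zero-padded so alphabetical order == index order
        return tuple(f"class{i:02d}" for i in range(self.n_classes))


def hi_lab_proportions() -> tuple[tuple[str, ...], np.ndarray]:
    """Class names and proportion vector of the 18-class reference table."""
    names = tuple(HI_LAB_CLASS_COUNTS)
    counts = np.array(list(HI_LAB_CLASS_COUNTS.values()), dtype=np.float64)
    return names, counts / counts.sum()


def apportion_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` items over a simplex vector.

    Deterministic and exact (counts always sum to ``n``); remainder seats go
    to the largest fractional parts, ties to the lower index.
    """
    p = np.asarray(proportions, dtype=np.float64)
    quota = p * n
    counts = np.floor(quota).astype(np.int64)
    short = n - int(counts.sum())
    if short > 0:
        frac = quota - counts
        # stable sort on (-frac, index) -> ties favour the lower index
        order = np.lexsort((np.arange(len(p)), -frac))
        counts[order[:short]] += 1
    return counts


def _class_centroids(
    spec: SyntheticSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-view class centroid matrices with shared/private signal mixing."""
    max_dim = max(d for _, d in spec.views)
    shared = rng.standard_normal((spec.n_classes, max_dim))
    rho = spec.view_correlation
    radius = spec.separation / math.sqrt(2.0)
    centroids: dict[str, np.ndarray] = {}
    for view_id, dim in spec.views:
        private = rng.standard_normal((spec.n_classes, dim))
        mix = math.sqrt(rho) * shared[:, :dim] + math.sqrt(1.0 - rho) * private
        norms = np.linalg.norm(mix, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        # random unit directions scaled so the expected pairwise centroid
        # distance is ~`separation` noise s.d. (two random unit vectors in
        # high dimension are near-orthogonal: distance ~ radius*sqrt(2))
        centroids[view_id] = radius * mix / norms
    return centroids


def _labels_from_counts(
    counts: np.ndarray, names: tuple[str, ...], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Integer labels in a deterministic shuffled order plus the permutation."""
    y = np.repeat(np.arange(len(counts)), counts)
    perm = rng.permutation(len(y))
    return y[perm], perm


def generate_synthetic_features(
    spec: SyntheticSpec,
) -> tuple[list[FeatureMatrix], np.ndarray, ClassTable]:
    """Generate one feature matrix per view plus labels and a class table.

    Each view ``v`` is built as ``x = centroid_v[class] + eps`` with unit
    Gaussian noise ``eps``; centroids mix a cross-view shared class signal
    (weight ``sqrt(view_correlation)``) with a view-private one.

    Returns
    -------
    views : list of FeatureMatrix (same order as ``spec.views``)
    labels : ndarray of class-name strings, one per sample
    table : ClassTable of the apportioned per-class counts
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.resolved_class_names()
    counts = apportion_counts(spec.class_proportions, spec.n_samples)
    centroids = _class_centroids(spec, rng)
    y, _ = _labels_from_counts(counts, names, rng)
    ids = default_sample_ids(spec.n_samples)
    views: list[FeatureMatrix] = []
    for view_id, dim in spec.views:
        noise = rng.standard_normal((spec.n_samples, dim))
        x = centroids[view_id][y] + noise
        views.append(FeatureMatrix(x, list(ids), source_id=view_id))
    labels = np.asarray([names[i] for i in y], dtype=object)
    table = make_class_table(list(names), counts.tolist())
    return views, labels, table


# ---------------------------------------------------------------------------
# glyph images
# ---------------------------------------------------------------------------

#: Shape parameterizations for up to 18 glyph classes, keyed by the morphology
#: vocabulary they caricature.  Fields: head semi-axes (fractions of the image
#: side), tail length (fraction), tail curvature (waviness amplitude), neck
#: half-width (fraction).  These are stylized shape priors for testing the
#: imaging pipeline, not anatomical models.
GLYPH_PARAMS: dict[str, tuple[float, float, float, float, float]] = {
    #                      head_rx head_ry tail_len curv  neck_w
    "AmorphHead":        (0.130, 0.075, 0.45, 0.30, 0.020),
    "AsymmetricNeck":    (0.105, 0.075, 0.45, 0.45, 0.034),
    "CurlyTail":         (0.105, 0.075, 0.40, 1.00, 0.020),
    "DoubleHead":        (0.150, 0.060, 0.45, 0.25, 0.020),
    "DoubleTail":        (0.105, 0.075, 0.50, 0.65, 0.044),
    "LongTail":          (0.100, 0.072, 0.62, 0.20, 0.020),
    "NarrowAcrosome":    (0.125, 0.050, 0.45, 0.25, 0.020),
    "Normal":            (0.105, 0.075, 0.48, 0.22, 0.024),
    "PinHead":           (0.048, 0.038, 0.48, 0.25, 0.016),
    "PyriformHead":      (0.135, 0.062, 0.46, 0.28, 0.022),
    "RoundHead":         (0.088, 0.086, 0.46, 0.25, 0.022),
    "ShortTail":         (0.105, 0.075, 0.24, 0.25, 0.024),
    "TaperedHead":       (0.150, 0.048, 0.46, 0.25, 0.020),
    "ThickNeck":         (0.105, 0.075, 0.45, 0.25, 0.055),
    "ThinNeck":          (0.105, 0.075, 0.45, 0.25, 0.008),
    "TwistedNeck":       (0.105, 0.075, 0.46, 0.80, 0.030),
    "TwistedTail":       (0.105, 0.075, 0.50, 0.90, 0.018),
    "VacuolatedHead":    (0.118, 0.080, 0.45, 0.25, 0.022),
}

_SUPERSAMPLE = 4


def _render_glyph(
    side: int,
    head_rx: float,
    head_ry: float,
    tail_len: float,
    curv: float,
    neck_w: float,
) -> np.ndarray:
    """Draw one sperm-like glyph (dark on white) anti-aliased via supersampling."""
    s = side * _SUPERSAMPLE
    img = Image.new("L", (s, s), 255)
    draw = ImageDraw.Draw(img)
    cx, cy = 0.28 * s, 0.50 * s
    # head ellipse
    draw.ellipse(
        [cx - head_rx * s, cy - head_ry * s, cx + head_rx * s, cy + head_ry * s],
        fill=20,
    )
    # tail: wavy polyline of tapering width starting at the head's right edge
    x0 = cx + head_rx * s * 0.95
    n_seg = 24
    pts = []
    for i in range(n_seg + 1):
        t = i / n_seg
        x = x0 + t * tail_len * s
        y = cy + curv * 0.14 * s * math.sin(2.0 * math.pi * t)
        pts.append((x, y))
    for i in range(n_seg):
        taper = 1.0 - 0.7 * (i / n_seg)
        w = max(1, int(round(2.0 * neck_w * s * taper)))
        draw.line([pts[i], pts[i + 1]], fill=20, width=w)
    small = img.resize((side, side), Image.LANCZOS)
    return np.asarray(small, dtype=np.uint8)


def generate_synthetic_images(
    spec: SyntheticSpec, image_side: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Render class-determined sperm-like glyphs with separation-scaled jitter.

    Shape parameters are looked up per class (``spec.class_names`` when given,
    otherwise the first ``n_classes`` glyph classes in alphabetical order) and
    perturbed by multiplicative Gaussian jitter with s.d. proportional to
    ``1/separation`` (clamped so separation 0 gives heavy but bounded jitter).

    Returns
    -------
    images : uint8 array of shape (n, image_side, image_side, 3); grayscale
        replicated onto 3 channels.
    labels : ndarray of class-name strings.
    """
    if image_side < 32:
        raise ValueError("image_side must be >= 32")
    if spec.n_classes > len(GLYPH_PARAMS):
        raise ValueError(
            f"at most {len(GLYPH_PARAMS)} distinct glyph classes are available"
        )
    if spec.class_names is not None:
        names = spec.class_names
        missing = [n for n in names if n not in GLYPH_PARAMS]
        if missing:
            raise ValueError(f"no glyph parameterization for classes: {missing}")
    else:
        names = tuple(sorted(GLYPH_PARAMS))[: spec.n_classes]
    rng = np.random.default_rng(spec.seed)
    counts = apportion_counts(spec.class_proportions, spec.n_samples)
    y, _ = _labels_from_counts(counts, names, rng)
    jitter = 0.25 / max(spec.separation, 0.25)
    images = np.empty((spec.n_samples, image_side, image_side, 3), dtype=np.uint8)
    for i, ci in enumerate(y):
        base = np.asarray(GLYPH_PARAMS[names[ci]], dtype=np.float64)
        params = base * np.clip(1.0 + jitter * rng.standard_normal(5), 0.4, 1.8)
        gray = _render_glyph(image_side, *params)
        images[i] = gray[:, :, None]
    labels = np.asarray([names[i] for i in y], dtype=object)
    return images, labels


def write_image_tree(
    images: np.ndarray, labels: np.ndarray, root: str
) -> None:
    """Write images to a class-per-subdirectory PNG tree (dataset layout)."""
    from pathlib import Path

    root_p = Path(root)
    counters: dict[str, int] = {}
    for img, lab in zip(images, labels):
        d = root_p / str(lab)
        d.mkdir(parents=True, exist_ok=True)
        k = counters.get(str(lab), 0)
        counters[str(lab)] = k + 1
        Image.fromarray(img).save(d / f"{lab}_{k:05d}.png")


# ---------------------------------------------------------------------------
# correlated prediction sources
# ---------------------------------------------------------------------------


def simulate_correlated_sources(
    n_samples: int,
    n_classes: int,
    n_sources: int = 3,
    accuracy: float = 0.7,
    error_correlation: float = 0.25,
    confidence: float = 0.8,
    seed: int = 0,
) -> tuple[list[ClassProbabilityMatrix], np.ndarray]:
    """Simulate per-source class-probability matrices with correlated errors.

    Each source predicts the true class with probability ``accuracy``.  With
    probability ``error_correlation`` a sample draws a *shared* correct/wrong
    indicator used by every source (errors co-occur); otherwise indicators are
    independent — so the pairwise correlation of error indicators equals
    ``error_correlation``.  Wrong labels are drawn independently per source.
    Probability rows put ``confidence`` (plus a small jitter, renormalized) on
    the predicted class and spread the rest uniformly.

    Returns the list of sources and the true label vector (class-name strings).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 <= error_correlation <= 1.0:
        raise ValueError("error_correlation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"class{i:02d}" for i in range(n_classes)]
    truth = rng.integers(0, n_classes, size=n_samples)
    shared_mask = rng.random(n_samples) < error_correlation
    shared_correct = rng.random(n_samples) < accuracy
    ids = default_sample_ids(n_samples)
    sources: list[ClassProbabilityMatrix] = []
    for k in range(n_sources):
        own_correct = rng.random(n_samples) < accuracy
        correct = np.where(shared_mask, shared_correct, own_correct)
        # wrong labels: uniform over the other classes, independent per source
        offset = rng.integers(1, n_classes, size=n_samples)
        predicted = np.where(correct, truth, (truth + offset) % n_classes)
        conf = np.clip(confidence + 0.05 * rng.standard_normal(n_samples), 0.5, 0.95)
        rest = (1.0 - conf) / (n_classes - 1)
        p = np.repeat(rest[:, None], n_classes, axis=1)
        p[np.arange(n_samples), predicted] = conf
        p /= p.sum(axis=1, keepdims=True)
        sources.append(
            ClassProbabilityMatrix(p, list(names), list(ids), source_id=f"source{k}")
        )
    labels = np.asarray([names[i] for i in truth], dtype=object)
    return sources, labels
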