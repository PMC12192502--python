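"""The three probability-emitting classifiers behind one fit/predict contract.

All three consume a (fused) feature matrix and emit aligned per-class
probability rows, which is what makes downstream soft voting possible:

* **one-vs-rest RBF-SVM** — one binary margin classifier per class on
  standardized features, kernel ``K(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2)``;
  (gamma, C) selected by inner cross-validated accuracy over a grid; per-class
  scores are Platt-calibrated sigmoids renormalized to sum to 1.
* **Random Forest** — T trees on bootstrap samples with random sqrt(d) feature
  subsets; the ensemble probability is the arithmetic mean of per-tree leaf
  class frequencies, and the label is its argmax.
* **attention-gated MLP (MLP-A)** — a feature-wise sigmoid attention gate
  ``A = sigmoid(W_attn f + b_attn)`` multiplies the input elementwise
  (``f_attended = A * f``) before a linear softmax head; the gate and head are
  trained jointly by cross-entropy.

Standardization (per-column ``(x - mu) / sigma``, population s.d., computed on
training rows only) is applied inside every ``fit_*`` so that feature scale
never leaks across the fit/predict boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from ._nn import Adam, cross_entropy, iterate_minibatches, sigmoid, softmax, train_val_split
from .containers import ClassProbabilityMatrix, FeatureMatrix

__all__ = [
    "Standardizer",
    "fit_standardizer",
    "standardize",
    "rbf_kernel",
    "SvmConfig",
    "fit_svm",
    "RfConfig",
    "fit_rf",
    "average_tree_probabilities",
    "AttentionMlp",
    "mlpa_forward",
    "MlpaConfig",
    "fit_mlpa",
    "FittedModel",
    "predict_proba",
    "predict_label",
    "save_model",
    "load_model",
]


def _as_array(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Per-column centering and unit-variance scaling, fitted on training rows.

    Population standard deviation is used; constant columns (sigma = 0) are
    centered only (divisor 1).
    """

    mu: np.ndarray
    sigma: np.ndarray

    def transform(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        arr = _as_array(X)
        if arr.shape[1] != self.mu.shape[0]:
            raise ValueError(
                f"dimension mismatch: standardizer has {self.mu.shape[0]} columns, "
                f"input has {arr.shape[1]}"
            )
        return (arr - self.mu) / self.sigma


def fit_standardizer(train: FeatureMatrix | np.ndarray) -> Standardizer:
    X = _as_array(train)
    if X.shape[0] == 0:
        raise ValueError("cannot fit a standardizer on an empty matrix")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)  # population s.d. (ddof=0)
    sigma = np.where(sigma == 0.0, 1.0, sigma)
    return Standardizer(mu, sigma)


def standardize(s: Standardizer, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    return s.transform(X)


# ---------------------------------------------------------------------------
# RBF kernel
# ---------------------------------------------------------------------------


def rbf_kernel(x_i: np.ndarray, x_j: np.ndarray, gamma: float) -> float:
    """``exp(-gamma * ||x_i - x_j||^2)``; symmetric, 1 at zero distance."""
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    if x_i.shape != x_j.shape:
        raise ValueError("dimension mismatch between kernel arguments")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d = x_i - x_j
    return float(np.exp(-gamma * np.dot(d, d)))


# ---------------------------------------------------------------------------
# fitted-model wrapper
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """A trained classifier plus everything needed to emit aligned probabilities."""

    kind: str  # "svm" | "rf" | "mlpa"
    class_order: list[str]
    standardizer: Standardizer | None
    estimator: Any
    config: dict = field(default_factory=dict)


def predict_proba(model: FittedModel, X: FeatureMatrix | np.ndarray) -> ClassProbabilityMatrix:
    """Per-class probability rows (summing to 1), columns in ``class_order``."""
    arr = _as_array(X)
    ids = X.sample_ids if isinstance(X, FeatureMatrix) else []
    if model.standardizer is not None:
        arr = model.standardizer.transform(arr)
    if model.kind == "mlpa":
        probs = mlpa_forward(model.estimator, arr)
    else:
        probs = model.estimator.predict_proba(arr)
        order = [list(model.estimator.classes_).index(c) for c in model.class_order]
        probs = probs[:, order]
    return ClassProbabilityMatrix(probs, list(model.class_order), list(ids), source_id=model.kind)


def predict_label(
    probs: ClassProbabilityMatrix | np.ndarray, class_order: list[str] | None = None
) -> np.ndarray:
    """Argmax class per row; ties broken by lowest class index."""
    if isinstance(probs, ClassProbabilityMatrix):
        return probs.labels()
    idx = np.argmax(np.asarray(probs), axis=1)
    if class_order is None:
        return idx
    return np.asarray([class_order[i] for i in idx], dtype=object)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


@dataclass
class SvmConfig:
    """Grid and inner-CV settings for one-vs-rest RBF-SVM tuning.

    ``gamma_grid`` entries may be positive floats or ``"scale"``
    (``1 / (d * var)`` on the standardized training matrix).  Selection is by
    mean inner-CV accuracy; ties prefer smaller C, then smaller gamma.
    """

    gamma_grid: tuple = ("scale", 1e-3, 1e-2, 1e-1)
    c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    inner_folds: int = 3
    kernel: str = "rbf"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.gamma_grid) == 0 or len(self.c_grid) == 0:
            raise ValueError("hyperparameter grid must be non-empty")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


def _resolve_gamma(gamma, X: np.ndarray) -> float:
    if gamma == "scale":
        var = X.var()
        return 1.0 / (X.shape[1] * var) if var > 0 else 1.0 / X.shape[1]
    g = float(gamma)
    if g <= 0:
        raise ValueError("gamma must be positive")
    return g


def fit_svm(
    train: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    config: SvmConfig | None = None,
) -> FittedModel:
    """One-vs-rest RBF-SVM with inner-CV hyperparameter selection.

    One binary margin classifier is trained per class against the rest on
    standardized features.  Per-class probabilities come from Platt-style
    sigmoid calibration of each binary classifier's decision values,
    renormalized across classes to sum to 1.
    """
    config = config or SvmConfig()
    labels = np.asarray(labels)
    X = _as_array(train)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    scaler = fit_standardizer(X)
    Xs = scaler.transform(X)

    candidates = [
        (_resolve_gamma(g, Xs), float(c)) for g in config.gamma_grid for c in config.c_grid
    ]
    if len(candidates) == 1:
        best_gamma, best_c = candidates[0]
    else:
        inner = config.inner_folds
        min_count = int(counts.min())
        if min_count < inner:
            inner = max(2, min_count)
            warnings.warn(
                f"smallest class has {min_count} samples; inner CV reduced to {inner} folds"
            )
        if min_count < 2:
            warnings.warn("a class has fewer than 2 samples; skipping grid selection")
            best_gamma, best_c = candidates[0]
        else:
            cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=config.seed)
            scored = []
            for gamma, c in candidates:
                est = OneVsRestClassifier(
                    SVC(kernel=config.kernel, gamma=gamma, C=c, cache_size=200)
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    acc = cross_val_score(est, Xs, labels, cv=cv, scoring="accuracy").mean()
                scored.append((acc, c, gamma))
            best_acc = max(s[0] for s in scored)
            ties = [s for s in scored if s[0] == best_acc]
            _, best_c, best_gamma = min(ties, key=lambda s: (s[1], s[2]))

    est = OneVsRestClassifier(
        SVC(
            kernel=config.kernel,
            gamma=best_gamma,
            C=best_c,
            probability=True,
            random_state=config.seed,
            cache_size=200,
        )
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xs, labels)
    return FittedModel(
        kind="svm",
        class_order=[str(c) for c in est.classes_],
        standardizer=scaler,
        estimator=est,
        config={"gamma": best_gamma, "C": best_c, "kernel": config.kernel, "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# Random Forest
# ---------------------------------------------------------------------------


@dataclass
class RfConfig:
    """Random-forest growth controls (T trees, bootstrap, sqrt(d) features)."""

    n_trees: int = 500
    max_depth: int | None = None
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def fit_rf(
    train: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    config: RfConfig | None = None,
) -> FittedModel:
    """Random Forest whose class probability is the mean of per-tree leaf
    frequencies (``P(y|x) = (1/T) sum_t P_t(y|x)``), label = argmax.

    Standardization is applied first for consistency with the other
    classifiers (trees themselves are scale-invariant, so this is harmless).
    """
    config = config or RfConfig()
    labels = np.asarray(labels)
    X = _as_array(train)
    scaler = fit_standardizer(X)
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_leaf,
        max_features="sqrt",
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(scaler.transform(X), labels)
    return FittedModel(
        kind="rf",
        class_order=[str(c) for c in est.classes_],
        standardizer=scaler,
        estimator=est,
        config={"n_trees": config.n_trees, "max_depth": config.max_depth,
                "min_leaf": config.min_leaf, "seed": config.seed},
    )


def average_tree_probabilities(tree_probs: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Arithmetic mean of per-tree probability rows — the forest's ensemble rule."""
    arr = np.asarray(tree_probs, dtype=np.float64)
    if arr.ndim < 2:
        raise ValueError("expected a stack of per-tree probability arrays")
    return arr.mean(axis=0)


# ---------------------------------------------------------------------------
# attention-gated MLP
# ---------------------------------------------------------------------------


@dataclass
class AttentionMlp:
    """Parameters of the attention-gated MLP (gate + linear softmax head)."""

    W_attn: np.ndarray  # (d, d)
    b_attn: np.ndarray  # (d,)
    W_final: np.ndarray  # (C, d)
    b_final: np.ndarray  # (C,)

    def __post_init__(self) -> None:
        d = self.W_attn.shape[0]
        if self.W_attn.shape != (d, d) or self.b_attn.shape != (d,):
            raise ValueError("attention parameters must be (d, d) and (d,)")
        if self.W_final.shape[1] != d or self.b_final.shape != (self.W_final.shape[0],):
            raise ValueError("head parameters must be (C, d) and (C,)")

    @property
    def d(self) -> int:
        return self.W_attn.shape[0]

    @property
    def n_classes(self) -> int:
        return self.W_final.shape[0]


def mlpa_forward(model: AttentionMlp, F: np.ndarray) -> np.ndarray:
    """Forward pass: sigmoid gate, elementwise weighting, linear head, softmax.

    ``A = sigmoid(W_attn F + b_attn)``; ``F_attended = A * F``;
    ``Y = W_final F_attended + b_final``; probabilities = softmax(Y) with
    max-subtraction.  Accepts one feature vector (returns shape ``(C,)``) or a
    matrix (returns ``(n, C)``).
    """
    F = np.asarray(F, dtype=np.float64)
    single = F.ndim == 1
    X = F[None, :] if single else F
    if X.shape[1] != model.d:
        raise ValueError(f"feature dim {X.shape[1]} does not match model d={model.d}")
    A = sigmoid(X @ model.W_attn.T + model.b_attn)
    attended = A * X
    logits = attended @ model.W_final.T + model.b_final
    probs = softmax(logits)
    return probs[0] if single else probs


def attention_weights(model: AttentionMlp, F: np.ndarray) -> np.ndarray:
    """The gate activations A (strictly inside (0,1) elementwise)."""
    F = np.asarray(F, dtype=np.float64)
    X = F[None, :] if F.ndim == 1 else F
    return sigmoid(X @ model.W_attn.T + model.b_attn)


@dataclass
class MlpaConfig:
    """Training knobs for the attention-gated MLP (batched Adam, early stop)."""

    batch_size: int = 64
    max_epochs: int = 300
    learning_rate: float = 1e-3
    patience: int = 15
    val_fraction: float = 0.1
    seed: int = 0
    standardize: bool = True


def fit_mlpa(
    train: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    config: MlpaConfig | None = None,
) -> FittedModel:
    """Train gate and head jointly by softmax cross-entropy (Adam, seeded).

    Weight init is scaled uniform; training aborts with a diagnostic if the
    loss becomes non-finite.  Deterministic given the config seed.
    """
    config = config or MlpaConfig()
    labels = np.asarray(labels)
    X = _as_array(train)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    scaler = fit_standardizer(X) if config.standardize else None
    Xs = scaler.transform(X) if scaler is not None else X
    n, d = Xs.shape
    c = len(classes)
    rng = np.random.default_rng(config.seed)
    lim_a = np.sqrt(6.0 / (2 * d))
    lim_f = np.sqrt(6.0 / (d + c))
    Wa = rng.uniform(-lim_a, lim_a, size=(d, d))
    ba = np.zeros(d)
    Wf = rng.uniform(-lim_f, lim_f, size=(c, d))
    bf = np.zeros(c)
    opt = Adam([Wa, ba, Wf, bf], lr=config.learning_rate)
    tr, va = train_val_split(n, config.val_fraction, rng)
    if len(va) == 0 or len(tr) == 0:
        tr, va = np.arange(n), np.arange(n)

    def logits_of(idx):
        A = sigmoid(Xs[idx] @ Wa.T + ba)
        H = A * Xs[idx]
        return A, H, H @ Wf.T + bf

    best = (np.inf, None)
    since_best = 0
    for _ in range(config.max_epochs):
        for batch in iterate_minibatches(len(tr), config.batch_size, rng):
            idx = tr[batch]
            A, H, logits = logits_of(idx)
            G = softmax(logits)
            G[np.arange(len(idx)), y[idx]] -= 1.0
            G /= len(idx)
            gWf = G.T @ H
            gbf = G.sum(axis=0)
            dH = G @ Wf
            dZ = dH * Xs[idx] * A * (1.0 - A)
            gWa = dZ.T @ Xs[idx]
            gba = dZ.sum(axis=0)
            opt.step([gWa, gba, gWf, gbf])
        _, _, logits_va = logits_of(va)
        loss = cross_entropy(logits_va, y[va])
        if not np.isfinite(loss):
            raise RuntimeError("MLP-A training diverged (non-finite validation loss)")
        if loss < best[0] - 1e-6:
            best = (loss, (Wa.copy(), ba.copy(), Wf.copy(), bf.copy()))
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    params = best[1] if best[1] is not None else (Wa, ba, Wf, bf)
    mlp = AttentionMlp(*params)
    return FittedModel(
        kind="mlpa",
        class_order=[str(cl) for cl in classes],
        standardizer=scaler,
        estimator=mlp,
        config={"seed": config.seed, "learning_rate": config.learning_rate,
                "batch_size": config.batch_size, "max_epochs": config.max_epochs,
                "patience": config.patience},
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist a fitted model (joblib) with a JSON manifest sidecar."""
    path = Path(path)
    joblib.dump(model, path)
    manifest = {"kind": model.kind, "class_order": model.class_order, "config": model.config}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def load_model(path: str | Path) -> FittedModel:
    return joblib.load(path)
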