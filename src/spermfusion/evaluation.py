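"""Evaluation harness: stratified K-fold CV, metrics, AUC, paired t-tests.

Conventions used throughout:

* cross-validation is stratified (per-class shuffled round-robin dealing), so
  per-class counts across folds differ by at most one even for a 42-sample
  class under K = 5;
* the headline accuracy of a CV run is the *unweighted mean of the K fold
  accuracies* (the pooled-prediction accuracy is also reported);
* per-class accuracy is class recall: the confusion-matrix diagonal over the
  row sum;
* AUC is one-vs-rest per class via the midrank Mann-Whitney statistic;
  classes absent from a test set get an undefined AUC (excluded from means);
* model comparison uses the two-sided paired t-test on fold accuracies
  (df = K-1); all-zero differences give t = 0, p = 1 by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .classtable import ClassTable
from .containers import ClassProbabilityMatrix

__all__ = [
    "FoldSplit",
    "stratified_kfold",
    "EvaluationReport",
    "score",
    "ovr_auc",
    "low_sample_report",
    "PairedTestResult",
    "paired_ttest",
]


# ---------------------------------------------------------------------------
# stratified K-fold
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    """Per-sample fold assignments for stratified K-fold cross-validation."""

    K: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == k)

    def train_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != k)

    def folds(self):
        for k in range(self.K):
            yield self.train_indices(k), self.test_indices(k)


def stratified_kfold(labels: np.ndarray, K: int = 5, seed: int = 0) -> FoldSplit:
    """Stratify by class: shuffle each class's samples, deal them round-robin.

    Every sample lands in exactly one fold and per-class fold counts differ by
    at most one (e.g. a 42-sample class under K = 5 splits as {9,9,8,8,8}).
    Dealing starts at fold ``class_index mod K`` so overall fold sizes stay
    balanced.  Classes with fewer than K samples are still dealt round-robin
    (with a warning): they simply miss some folds.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError("K cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=np.int64)
    classes = np.unique(labels)
    for ci, cls in enumerate(classes):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < K:
            warnings.warn(f"class {cls!r} has {len(idx)} samples (< K={K})")
        idx = rng.permutation(idx)
        for j, sample in enumerate(idx):
            assignments[sample] = (ci + j) % K
    return FoldSplit(K, assignments, seed)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def ovr_auc(truth: np.ndarray, scores: np.ndarray) -> float:
    """One-vs-rest AUC for one class via the midrank Mann-Whitney statistic.

    ``truth`` is a boolean positive-class indicator, ``scores`` the class's
    probability column.  Returns NaN when either group is empty.
    """
    truth = np.asarray(truth, dtype=bool)
    pos = int(truth.sum())
    neg = len(truth) - pos
    if pos == 0 or neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average (mid) ranks on ties
    u = ranks[truth].sum() - pos * (pos + 1) / 2.0
    return float(u / (pos * neg))


@dataclass
class EvaluationReport:
    """Overall and per-class metrics for one set of predictions."""

    class_order: list[str]
    overall_accuracy: float  # percent
    per_class_accuracy: dict[str, float]  # percent (recall); NaN if class absent
    confusion: np.ndarray  # C x C counts, rows = truth
    auc: dict[str, float] = field(default_factory=dict)  # NaN where undefined
    fold_accuracies: list[float] = field(default_factory=list)  # percent
    mean_std: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "class_order": self.class_order,
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion": self.confusion.tolist(),
            "auc": self.auc,
        }
        if self.fold_accuracies:
            d["fold_accuracies"] = self.fold_accuracies
            d["mean_std"] = list(self.mean_std)
        return d


def score(
    predictions: np.ndarray,
    truth: np.ndarray,
    probabilities: ClassProbabilityMatrix | None = None,
    class_order: list[str] | None = None,
) -> EvaluationReport:
    """Accuracy, per-class recall, confusion matrix and (optionally) OvR AUC.

    ``class_order`` defaults to the probability matrix's order, else to the
    sorted union of predicted and true labels.  Classes absent from ``truth``
    get NaN per-class accuracy and NaN AUC and are excluded from averages.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth have different lengths")
    if class_order is None:
        if probabilities is not None:
            class_order = list(probabilities.class_order)
        else:
            class_order = sorted(set(map(str, predictions)) | set(map(str, truth)))
    index = {c: i for i, c in enumerate(class_order)}
    unknown = set(map(str, predictions)) | set(map(str, truth))
    unknown -= set(class_order)
    if unknown:
        raise ValueError(f"labels outside the class order: {sorted(unknown)}")
    C = len(class_order)
    confusion = np.zeros((C, C), dtype=np.int64)
    for t, p in zip(truth, predictions):
        confusion[index[str(t)], index[str(p)]] += 1
    overall = 100.0 * np.trace(confusion) / len(truth)
    row_sums = confusion.sum(axis=1)
    per_class = {
        c: (100.0 * confusion[i, i] / row_sums[i]) if row_sums[i] > 0 else float("nan")
        for i, c in enumerate(class_order)
    }
    auc: dict[str, float] = {}
    if probabilities is not None:
        if probabilities.n_samples != len(truth):
            raise ValueError("probabilities and truth have different lengths")
        truth_str = np.asarray([str(t) for t in truth])
        for c in class_order:
            j = probabilities.class_order.index(c)
            auc[c] = ovr_auc(truth_str == c, probabilities.values[:, j])
    return EvaluationReport(list(class_order), overall, per_class, confusion, auc)


def low_sample_report(
    report: EvaluationReport, class_table: ClassTable, threshold_percent: float
) -> pd.DataFrame:
    """Per-class accuracy for classes whose share falls below a threshold.

    Mirrors the low-sample-class analysis convention: a class is "low sample"
    when its percentage share of the dataset is strictly below
    ``threshold_percent`` (2.5 selects the six rarest classes of the 18-class
    reference table).
    """
    rows = []
    for name, share in zip(class_table.names, class_table.shares):
        if share < threshold_percent:
            rows.append(
                {
                    "class": name,
                    "share_percent": share,
                    "accuracy_percent": report.per_class_accuracy.get(name, float("nan")),
                }
            )
    return pd.DataFrame(rows, columns=["class", "share_percent", "accuracy_percent"])


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    """Two-sided paired t-test between two models' fold accuracies."""

    group_ids: tuple[str, str]
    means_stds: tuple[tuple[float, float], tuple[float, float]]
    t_stat: float
    p_value: float
    reject: bool
    best: str  # winning model id, or "none"


def paired_ttest(
    acc_a: np.ndarray,
    acc_b: np.ndarray,
    alpha: float = 0.05,
    ids: tuple[str, str] = ("A", "B"),
) -> PairedTestResult:
    """Two-sided paired t-test on fold-wise accuracy differences (df = K-1).

    Fold accuracies must be paired (same folds for both models).  Identical
    vectors give t = 0, p = 1 by convention.  ``best`` is the higher-mean
    model when the null is rejected at ``alpha``, else "none".
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("fold-accuracy vectors have different lengths")
    if len(a) < 2:
        raise ValueError("need at least 2 folds")
    diffs = a - b
    if np.all(diffs == 0.0) or np.std(diffs, ddof=1) == 0.0 and np.mean(diffs) == 0.0:
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_rel(a, b)
        t_stat, p_value = float(t_stat), float(p_value)
    reject = p_value < alpha
    means_stds = (
        (float(a.mean()), float(a.std(ddof=1))),
        (float(b.mean()), float(b.std(ddof=1))),
    )
    if reject:
        best = ids[0] if a.mean() > b.mean() else ids[1]
    else:
        best = "none"
    return PairedTestResult(tuple(ids), means_stds, t_stat, p_value, reject, best)
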