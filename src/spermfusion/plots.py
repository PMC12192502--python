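"""Confusion-matrix and one-vs-rest ROC renderings of evaluation reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.metrics import roc_curve

from .containers import ClassProbabilityMatrix
from .evaluation import EvaluationReport

__all__ = ["plot_confusion", "plot_roc"]


def plot_confusion(report: EvaluationReport, path: str | Path) -> None:
    """Heatmap of the confusion matrix (rows = truth, columns = prediction)."""
    fig, ax = plt.subplots(figsize=(0.5 * len(report.class_order) + 3,) * 2)
    im = ax.imshow(report.confusion, cmap="Blues")
    ax.set_xticks(range(len(report.class_order)), report.class_order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(report.class_order)), report.class_order, fontsize=7)
    ax.set_xlabel("Predicted class")
    ax.set_ylabel("True class")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(
    truth: np.ndarray, probabilities: ClassProbabilityMatrix, path: str | Path
) -> None:
    """One-vs-rest ROC curve per class, annotated with its AUC."""
    from .evaluation import ovr_auc

    truth = np.asarray([str(t) for t in truth])
    fig, ax = plt.subplots(figsize=(6, 6))
    for j, cls in enumerate(probabilities.class_order):
        pos = truth == cls
        if pos.sum() == 0 or pos.sum() == len(pos):
            continue
        fpr, tpr, _ = roc_curve(pos, probabilities.values[:, j])
        auc = ovr_auc(pos, probabilities.values[:, j])
        ax.plot(fpr, tpr, lw=1, label=f"{cls} (AUC={auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
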