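"""Experiment orchestration: the extract → reduce → fuse → classify → vote →
evaluate workflow driven by one declarative configuration.

A run takes multi-view features (synthetic or from files), optionally reduces
each view with the trainable dense layer (fitted on training folds only),
builds the configured fusion combinations, cross-validates every classifier
on every combination with one shared stratified fold split, soft-votes the
configured classifier sets per combination, and finishes with paired t-tests
between all cells that share a fold protocol.  All randomness flows from one
master seed via fixed per-stage offsets, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifiers import (
    FittedModel,
    MlpaConfig,
    RfConfig,
    SvmConfig,
    fit_mlpa,
    fit_rf,
    fit_svm,
    predict_proba,
)
from .classtable import ClassTable
from .containers import ClassProbabilityMatrix, FeatureMatrix
from .evaluation import (
    EvaluationReport,
    PairedTestResult,
    paired_ttest,
    score,
    stratified_kfold,
)
from .fusion import concat_features, enumerate_fusions
from .reduction import ReductionTrainConfig, apply_reduction, fit_reduction
from .synthetic import SyntheticSpec, generate_synthetic_features, hi_lab_proportions
from .voting import VoteInput, soft_vote

__all__ = ["RunConfig", "ExperimentResult", "run_experiment", "cross_validate_models"]


@dataclass
class RunConfig:
    """Declarative description of one experiment grid.

    Data enters either as a synthetic spec (``synthetic``) or as per-view
    feature CSV paths (``feature_files`` + ``labels_file``).  ``fusions``
    lists view-id combinations ("auto" = each single view, the three pairs
    and the triple when exactly three views exist).
    """

    synthetic: dict | None = None
    feature_files: dict[str, str] | None = None
    labels_file: str | None = None
    reduction: dict = field(default_factory=lambda: {"enabled": False, "out_dim": 128})
    fusions: list[list[str]] | str = "auto"
    classifiers: list[str] = field(default_factory=lambda: ["svm", "rf", "mlpa"])
    classifier_params: dict = field(default_factory=dict)
    vote_sets: list[list[str]] = field(default_factory=lambda: [["svm", "rf", "mlpa"]])
    K: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def load_data(self) -> tuple[list[FeatureMatrix], np.ndarray, ClassTable | None]:
        if self.synthetic is not None:
            kwargs = dict(self.synthetic)
            if kwargs.pop("hi_lab_profile", False):
                names, props = hi_lab_proportions()
                kwargs.setdefault("n_classes", len(names))
                kwargs.setdefault("class_proportions", props.tolist())
                kwargs.setdefault("class_names", list(names))
            if "class_proportions" not in kwargs:
                n = kwargs["n_classes"]
                kwargs["class_proportions"] = [1.0 / n] * n
            kwargs.setdefault("seed", self.seed)
            spec = SyntheticSpec(**kwargs)
            return generate_synthetic_features(spec)
        if self.feature_files is None or self.labels_file is None:
            raise ValueError("config needs either 'synthetic' or feature/labels files")
        views = [
            FeatureMatrix.from_csv(path, source_id=vid)
            for vid, path in self.feature_files.items()
        ]
        labels = pd.read_csv(self.labels_file)["label"].astype(str).to_numpy()
        return views, labels, None

    def resolve_fusions(self, view_ids: list[str]) -> list[tuple[str, ...]]:
        if self.fusions == "auto":
            combos: list[tuple[str, ...]] = [(v,) for v in view_ids]
            if len(view_ids) == 3:
                combos += enumerate_fusions(view_ids)
            return combos
        resolved = []
        for combo in self.fusions:
            unknown = [v for v in combo if v not in view_ids]
            if unknown:
                raise ValueError(f"fusion references unknown view ids: {unknown}")
            resolved.append(tuple(combo))
        return resolved


@dataclass
class ExperimentResult:
    """All per-cell reports plus pairwise fold-accuracy comparisons."""

    reports: dict[str, EvaluationReport]  # "combo/model" -> report
    ttests: list[PairedTestResult]
    class_table: ClassTable | None
    config: RunConfig

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, rep in self.reports.items():
            combo, model = name.rsplit("/", 1)
            mean, std = rep.mean_std if rep.mean_std else (rep.overall_accuracy, 0.0)
            rows.append(
                {
                    "combo": combo,
                    "model": model,
                    "fold_mean_accuracy": round(mean, 4),
                    "fold_std_accuracy": round(std, 4),
                    "pooled_accuracy": round(rep.overall_accuracy, 4),
                }
            )
        return pd.DataFrame(rows)

    def ttest_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.ttests:
            (m1, s1), (m2, s2) = t.means_stds
            rows.append(
                {
                    "group_1": t.group_ids[0],
                    "group_2": t.group_ids[1],
                    "mean_std_1": f"{m1:.2f} ± {s1:.2f}",
                    "mean_std_2": f"{m2:.2f} ± {s2:.2f}",
                    "t_stat": round(t.t_stat, 6),
                    "p_value": round(t.p_value, 6),
                    "reject": t.reject,
                    "best": t.best,
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        """Write report.json / summary.csv / ttests.csv (timestamp-free,
        deterministic byte-for-byte for a fixed config and seed)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {name: rep.to_dict() for name, rep in self.reports.items()}
        (out / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        self.summary_frame().to_csv(out / "summary.csv", index=False)
        self.ttest_frame().to_csv(out / "ttests.csv", index=False)


_FITTERS = {
    "svm": (fit_svm, SvmConfig),
    "rf": (fit_rf, RfConfig),
    "mlpa": (fit_mlpa, MlpaConfig),
}


def _fit_one(kind: str, X: np.ndarray, y: np.ndarray, params: dict, seed: int) -> FittedModel:
    fitter, cfg_cls = _FITTERS[kind]
    cfg = cfg_cls(**{**params, "seed": seed})
    return fitter(X, y, cfg)


def cross_validate_models(
    features: FeatureMatrix,
    labels: np.ndarray,
    kinds: list[str],
    vote_sets: list[list[str]],
    K: int = 5,
    seed: int = 0,
    classifier_params: dict | None = None,
) -> dict[str, EvaluationReport]:
    """Stratified K-fold CV of several classifiers plus their soft votes.

    All classifiers share the same fold split, so their fold accuracies are
    paired (the requirement for the paired t-test) and their per-fold
    probability matrices are aligned for voting.  Reports carry pooled
    confusion matrices, per-fold accuracies and the fold-mean ± s.d.
    """
    classifier_params = classifier_params or {}
    y = np.asarray(labels)
    split = stratified_kfold(y, K=K, seed=seed)
    class_order = sorted(np.unique(y.astype(str)))
    names = list(kinds) + ["+".join(vs) for vs in vote_sets]
    fold_acc: dict[str, list[float]] = {n: [] for n in names}
    pooled_pred: dict[str, list[np.ndarray]] = {n: [] for n in names}
    pooled_probs: dict[str, list[np.ndarray]] = {n: [] for n in names}
    pooled_truth: list[np.ndarray] = []
    pooled_ids: list[list[str]] = []
    for k, (tr, te) in enumerate(split.folds()):
        Xtr = FeatureMatrix(
            features.values[tr], [features.sample_ids[i] for i in tr], features.source_id
        )
        Xte = FeatureMatrix(
            features.values[te], [features.sample_ids[i] for i in te], features.source_id
        )
        fold_probs: dict[str, ClassProbabilityMatrix] = {}
        for kind in kinds:
            model = _fit_one(kind, Xtr.values, y[tr], classifier_params.get(kind, {}), seed + 1000 + k)
            probs = predict_proba(model, Xte)
            if probs.class_order != class_order:
                raise RuntimeError("class order mismatch across folds")
            fold_probs[kind] = probs
        for vs in vote_sets:
            vote_name = "+".join(vs)
            fused, _ = soft_vote(VoteInput([(m, fold_probs[m]) for m in vs]))
            fold_probs[vote_name] = fused
        truth_te = y[te].astype(str)
        pooled_truth.append(truth_te)
        pooled_ids.append(Xte.sample_ids)
        for name in names:
            probs = fold_probs[name]
            pred = probs.labels()
            fold_acc[name].append(100.0 * float(np.mean(pred == truth_te)))
            pooled_pred[name].append(pred)
            pooled_probs[name].append(probs.values)
    truth_all = np.concatenate(pooled_truth)
    ids_all = [sid for chunk in pooled_ids for sid in chunk]
    reports: dict[str, EvaluationReport] = {}
    for name in names:
        pred_all = np.concatenate(pooled_pred[name])
        probs_all = ClassProbabilityMatrix(
            np.vstack(pooled_probs[name]), class_order, ids_all, source_id=name
        )
        rep = score(pred_all, truth_all, probs_all, class_order)
        rep.fold_accuracies = [round(a, 10) for a in fold_acc[name]]
        accs = np.asarray(fold_acc[name])
        rep.mean_std = (float(accs.mean()), float(accs.std(ddof=1)))
        reports[name] = rep
    return reports


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> ExperimentResult:
    """Execute the full grid: every fusion combination × every classifier and
    vote set, with per-fold reduction when enabled, then pairwise t-tests
    between all cells of each combination."""
    views, labels, class_table = config.load_data()
    by_id = {v.source_id: v for v in views}
    combos = config.resolve_fusions(list(by_id))
    reduce_on = bool(config.reduction.get("enabled", False))
    out_dim = int(config.reduction.get("out_dim", 128))

    reports: dict[str, EvaluationReport] = {}
    fold_accs: dict[str, list[float]] = {}
    for combo in combos:
        combo_name = "+".join(combo)
        parts = [by_id[v] for v in combo]
        if reduce_on:
            # reduction is per-view but must not see test folds: fit on a
            # stratified 80% of the data once per view (seeded), which keeps
            # the grid tractable while the classifiers' own CV stays clean
            parts = [_reduced_view(v, labels, out_dim, config.seed) for v in parts]
        fused = concat_features(parts).matrix if len(parts) > 1 else parts[0]
        cell_reports = cross_validate_models(
            fused,
            labels,
            config.classifiers,
            config.vote_sets,
            K=config.K,
            seed=config.seed,
            classifier_params=config.classifier_params,
        )
        for model_name, rep in cell_reports.items():
            key = f"{combo_name}/{model_name}"
            reports[key] = rep
            fold_accs[key] = rep.fold_accuracies

    ttests: list[PairedTestResult] = []
    for combo in combos:
        combo_name = "+".join(combo)
        cell_names = [k for k in reports if k.rsplit("/", 1)[0] == combo_name]
        for i in range(len(cell_names)):
            for j in range(i + 1, len(cell_names)):
                a, b = cell_names[i], cell_names[j]
                ttests.append(
                    paired_ttest(fold_accs[a], fold_accs[b], ids=(a, b))
                )
    result = ExperimentResult(reports, ttests, class_table, config)
    if out_dir is not None:
        result.write(out_dir)
    return result


def _reduced_view(
    view: FeatureMatrix, labels: np.ndarray, out_dim: int, seed: int
) -> FeatureMatrix:
    split = stratified_kfold(np.asarray(labels), K=5, seed=seed + 7)
    fit_idx = split.train_indices(0)
    layer = fit_reduction(
        view.values[fit_idx],
        np.asarray(labels)[fit_idx],
        out_dim=out_dim,
        config=ReductionTrainConfig(seed=seed + 7),
    )
    return apply_reduction(layer, view)
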