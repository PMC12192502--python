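"""In-memory containers shared across the pipeline.

Two tabular containers travel between every stage: a ``FeatureMatrix``
(one row of real-valued embedding features per sample) and a
``ClassProbabilityMatrix`` (one row of per-class probabilities per sample,
rows summing to 1).  Both round-trip through plain CSV so that any stage
can be driven from files produced by another tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "ClassProbabilityMatrix", "default_sample_ids"]


def default_sample_ids(n: int) -> list[str]:
    """Zero-padded sample identifiers ``s000000`` … used when none are given."""
    return [f"s{i:06d}" for i in range(n)]


@dataclass
class FeatureMatrix:
    """n x D matrix of embedding features from one backbone (or a fusion).

    Parameters
    ----------
    values
        Array of shape ``(n_samples, dim)``; always stored as float64.
    sample_ids
        One identifier per row; generated if omitted.
    source_id
        Identifier of the producing backbone / fusion (e.g. ``"v2s"``).
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    source_id: str = "features"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D array")
        if not self.sample_ids:
            self.sample_ids = default_sample_ids(self.values.shape[0])
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path, manifest: dict | None = None) -> None:
        """Write ``sample_id,f0,…,fD-1`` CSV plus an optional JSON sidecar."""
        path = Path(path)
        cols = [f"f{j}" for j in range(self.dim)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)
        if manifest is not None:
            meta = {"source_id": self.source_id, "dim": self.dim, **manifest}
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2, sort_keys=True) + "\n"
            )

    @classmethod
    def from_csv(cls, path: str | Path, source_id: str | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns:
            raise ValueError(f"{path}: missing 'sample_id' column")
        ids = df["sample_id"].astype(str).tolist()
        values = df.drop(columns="sample_id").to_numpy(dtype=np.float64)
        return cls(values, ids, source_id or Path(path).stem)


@dataclass
class ClassProbabilityMatrix:
    """n x C per-class probabilities, rows summing to 1, columns in class_order."""

    values: np.ndarray
    class_order: list[str]
    sample_ids: list[str] = field(default_factory=list)
    source_id: str = "probabilities"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("probability values must be a 2-D array")
        if self.values.shape[1] != len(self.class_order):
            raise ValueError("class_order length does not match column count")
        if not self.sample_ids:
            self.sample_ids = default_sample_ids(self.values.shape[0])
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def labels(self) -> np.ndarray:
        """Predicted label per row: argmax, ties broken by lowest class index."""
        idx = np.argmax(self.values, axis=1)
        return np.asarray([self.class_order[i] for i in idx], dtype=object)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.class_order)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source_id: str | None = None) -> "ClassProbabilityMatrix":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns:
            raise ValueError(f"{path}: missing 'sample_id' column")
        ids = df["sample_id"].astype(str).tolist()
        classes = [c for c in df.columns if c != "sample_id"]
        values = df[classes].to_numpy(dtype=np.float64)
        return cls(values, classes, ids, source_id or Path(path).stem)
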