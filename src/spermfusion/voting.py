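"""Decision-level fusion: soft voting over aligned class-probability matrices.

Each of K classifiers contributes a probability distribution per sample; the
fused decision is the class with the highest cumulative probability,
``y* = argmax_y sum_k p_k(y|x)``.  The fused matrix stored here is the
arithmetic *mean* of the sources (so it remains a probability matrix); the
argmax is identical to the sum's.  All voters carry equal weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import ClassProbabilityMatrix

__all__ = ["VoteInput", "soft_vote", "align_sources"]

_ROW_SUM_TOL = 1e-3  # renormalize-with-warning band for ingested CSVs


@dataclass
class VoteInput:
    """K aligned probability sources sharing class order and sample order."""

    sources: list[tuple[str, ClassProbabilityMatrix]]

    def __post_init__(self) -> None:
        if len(self.sources) == 0:
            raise ValueError("soft voting needs at least one source")
        first = self.sources[0][1]
        for sid, m in self.sources:
            if m.values.shape != first.values.shape:
                raise ValueError(f"source {sid!r}: shape mismatch")
            if m.class_order != first.class_order:
                raise ValueError(f"source {sid!r}: class_order mismatch")
            if m.sample_ids != first.sample_ids:
                raise ValueError(f"source {sid!r}: sample misalignment")
            sums = m.values.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError(f"source {sid!r}: probability rows do not sum to 1")

    @property
    def class_order(self) -> list[str]:
        return self.sources[0][1].class_order

    @property
    def sample_ids(self) -> list[str]:
        return self.sources[0][1].sample_ids


def soft_vote(vote_input: VoteInput) -> tuple[ClassProbabilityMatrix, np.ndarray]:
    """Average the source probability rows and take the argmax label.

    Returns the fused :class:`ClassProbabilityMatrix` (rows sum to 1) and the
    label vector (ties broken by lowest class index).  Invariant under
    permutation of the sources; with K = 1 it reproduces the single source.
    """
    stacked = np.stack([m.values for _, m in vote_input.sources])
    fused_values = stacked.mean(axis=0)
    fused = ClassProbabilityMatrix(
        fused_values,
        list(vote_input.class_order),
        list(vote_input.sample_ids),
        source_id="+".join(sid for sid, _ in vote_input.sources),
    )
    return fused, fused.labels()


def align_sources(files: list[str | Path]) -> VoteInput:
    """Read probability CSVs and align them to a canonical class/sample order.

    Columns are reordered to the sorted class set; rows are matched by
    ``sample_id`` to the first file's order.  Rows whose sums deviate from 1
    by at most 1e-3 are renormalized with a warning; larger deviations are
    rejected.  Missing sample ids or differing class sets are errors.
    """
    if not files:
        raise ValueError("no probability files given")
    raw = [ClassProbabilityMatrix.from_csv(f) for f in files]
    canonical_classes = sorted(raw[0].class_order)
    canonical_ids = list(raw[0].sample_ids)
    sources = []
    for path, m in zip(files, raw):
        if sorted(m.class_order) != canonical_classes:
            raise ValueError(f"{path}: class set differs from the first source")
        col = [m.class_order.index(c) for c in canonical_classes]
        values = m.values[:, col]
        id_pos = {sid: i for i, sid in enumerate(m.sample_ids)}
        missing = [sid for sid in canonical_ids if sid not in id_pos]
        if missing or len(m.sample_ids) != len(canonical_ids):
            raise ValueError(f"{path}: sample ids do not match the first source")
        rows = [id_pos[sid] for sid in canonical_ids]
        values = values[rows]
        sums = values.sum(axis=1)
        off = np.abs(sums - 1.0)
        if np.any(off > _ROW_SUM_TOL):
            worst = float(off.max())
            raise ValueError(
                f"{path}: probability rows deviate from sum 1 by up to {worst:.3g}"
            )
        if np.any(off > 1e-9):
            warnings.warn(f"{path}: renormalizing rows with sums off by <= {_ROW_SUM_TOL}")
            values = values / sums[:, None]
        sources.append(
            (
                Path(path).stem,
                ClassProbabilityMatrix(
                    values, list(canonical_classes), list(canonical_ids), Path(path).stem
                ),
            )
        )
    return VoteInput(sources)
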