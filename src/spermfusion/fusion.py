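"""Feature-level fusion: concatenation of per-backbone feature matrices.

Fusion stacks embeddings along the feature axis with no rescaling (any
standardization is the classifier's responsibility, applied downstream).
With three 1280-dimensional backbone embeddings this yields 2560 columns for
each pairwise combination and 3840 for the triple; with reduced 128-dim
embeddings, 256 and 384 respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FeatureMatrix

__all__ = ["FusedFeatures", "concat_features", "enumerate_fusions"]


@dataclass
class FusedFeatures:
    """Concatenated feature matrix with per-part column-range bookkeeping."""

    matrix: FeatureMatrix
    parts: list[tuple[str, int, tuple[int, int]]]  # (source id, dim, [start, stop))

    def part_block(self, source_id: str) -> np.ndarray:
        """Extract the contiguous column block contributed by one part."""
        for sid, _, (start, stop) in self.parts:
            if sid == source_id:
                return self.matrix.values[:, start:stop]
        raise KeyError(source_id)

    @property
    def dim(self) -> int:
        return self.matrix.dim

    def parts_manifest(self) -> dict:
        return {
            "parts": [
                {"source_id": sid, "dim": d, "columns": [start, stop]}
                for sid, d, (start, stop) in self.parts
            ],
            "total_dim": self.dim,
        }


def concat_features(parts: list[FeatureMatrix]) -> FusedFeatures:
    """Concatenate feature matrices along the feature dimension.

    All parts must carry the same samples in the same order (checked via
    sample ids); values are copied untouched, part *k* occupying the *k*-th
    contiguous column block.
    """
    if not parts:
        raise ValueError("empty part list")
    first = parts[0]
    for p in parts[1:]:
        if p.n_samples != first.n_samples:
            raise ValueError("row-count mismatch between parts")
        if p.sample_ids != first.sample_ids:
            raise ValueError("sample-id mismatch between parts")
    blocks = []
    meta = []
    start = 0
    for p in parts:
        blocks.append(p.values)
        meta.append((p.source_id, p.dim, (start, start + p.dim)))
        start += p.dim
    fused_id = "+".join(p.source_id for p in parts)
    fused = FeatureMatrix(np.hstack(blocks), list(first.sample_ids), source_id=fused_id)
    return FusedFeatures(fused, meta)


def enumerate_fusions(backbone_ids: list[str]) -> list[tuple[str, ...]]:
    """The three pairwise combinations plus the triple, in canonical order.

    For ids (s, m, l) this is [(s,m), (s,l), (m,l), (s,m,l)] — the order in
    which fusion grids are reported.
    """
    if len(backbone_ids) != 3:
        raise ValueError("exactly 3 backbone ids are required")
    if len(set(backbone_ids)) != 3:
        raise ValueError("backbone ids must be distinct")
    a, b, c = backbone_ids
    return [(a, b), (a, c), (b, c), (a, b, c)]
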