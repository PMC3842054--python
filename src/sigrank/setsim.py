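"""Overlap similarity between gene signatures.

Two indices are provided.  The overlap index (Jaccard) between signatures
A and B is |A∩B| / |A∪B|, ranging from 0 (disjoint) to 1 (identical).
The Kuncheva index additionally corrects for the overlap two random
size-``t`` subsets of ``N`` genes would share by chance,

    K(A, B) = (|A∩B| − t²/N) / (t − t²/N),

ranging from about 0 for chance-level overlap to 1 for identity (and
slightly negative below chance).  For the small signatures typical of
biomarker studies (t ≈ 10 out of thousands of genes) the correction term
is negligible and K ≈ |A∩B|/t.

Pairwise comparisons across M signatures are collected in a symmetric
:class:`SimilarityMatrix`; the overall agreement is the mean of its
off-diagonal entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datasets import GeneSet

__all__ = [
    "SimilarityMatrix",
    "overlap_similarity",
    "kuncheva_index",
    "pairwise_similarity_matrix",
    "average_offdiagonal",
]


@dataclass
class SimilarityMatrix:
    """Symmetric M×M matrix of pairwise signature similarities."""

    labels: list[str]
    values: np.ndarray
    index_name: str = "I-overlap"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.labels)
        if self.values.shape != (m, m):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label=self.index_name)

    def to_dict(self) -> dict:
        return {
            "index": self.index_name,
            "labels": list(self.labels),
            "values": self.values.tolist(),
            "average_offdiagonal": average_offdiagonal(self),
        }


def overlap_similarity(a: GeneSet, b: GeneSet) -> float:
    """Jaccard overlap |a∩b| / |a∪b| in [0, 1]."""
    sa, sb = set(a.genes), set(b.genes)
    if not sa or not sb:
        raise ValueError("overlap similarity is undefined for empty sets")
    return len(sa & sb) / len(sa | sb)


def kuncheva_index(a: GeneSet, b: GeneSet, n_total: int) -> float:
    """Chance-corrected overlap for equal-sized signatures from ``n_total`` genes."""
    sa, sb = set(a.genes), set(b.genes)
    if len(sa) != len(sb):
        raise ValueError(f"Kuncheva index needs equal-sized sets, got {len(sa)} and {len(sb)}")
    t = len(sa)
    if t == 0:
        raise ValueError("Kuncheva index is undefined for empty sets")
    if t >= n_total:
        raise ValueError("Kuncheva index is undefined when t >= total gene count")
    expected = t * t / n_total
    return (len(sa & sb) - expected) / (t - expected)


def pairwise_similarity_matrix(
    sets: Sequence[GeneSet],
    index: Callable[..., float] = overlap_similarity,
    n_total: int | None = None,
    labels: Sequence[str] | None = None,
    index_name: str | None = None,
) -> SimilarityMatrix:
    """Evaluate ``index`` on every pair of signatures, mirrored, diagonal = self-similarity."""
    m = len(sets)
    if labels is None:
        labels = [s.source_ranker or f"set{i}" for i, s in enumerate(sets)]
    kwargs = {} if n_total is None else {"n_total": n_total}
    values = np.ones((m, m))
    for i in range(m):
        values[i, i] = index(sets[i], sets[i], **kwargs)
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = index(sets[i], sets[j], **kwargs)
    if index_name is None:
        index_name = "Kuncheva" if index is kuncheva_index else "I-overlap"
    return SimilarityMatrix(labels=list(labels), values=values, index_name=index_name)


def average_offdiagonal(matrix: SimilarityMatrix) -> float:
    """Mean pairwise similarity over the M(M−1)/2 distinct pairs (diagonal excluded)."""
    m = len(matrix.labels)
    if m < 2:
        raise ValueError("need at least 2 sets to average pairwise similarity")
    iu = np.triu_indices(m, k=1)
    return float(matrix.values[iu].mean())
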