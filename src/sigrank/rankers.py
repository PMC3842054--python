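"""Eight feature-ranking methods for two-class expression data.

Univariate scorers evaluate each gene independently against the class:

* ``CHI2`` — Pearson χ² of the discretized-gene × class contingency table
* ``IG``   — information gain, H(C) − H(C|X), in bits
* ``SU``   — symmetrical uncertainty, 2·IG / (H(C) + H(X))
* ``GR``   — gain ratio, IG / H(X) (0 when H(X) = 0)
* ``ONER`` — training accuracy (%) of a one-gene bucket rule

Multivariate rankers account for gene interdependencies:

* ``RELIEFF``  — nearest hit/miss margin weights (k neighbours per class)
* ``SVM_ONE``  — squared weights of a single linear soft-margin SVM
* ``SVM_RFE``  — recursive feature elimination, refitting the SVM and
  dropping the lowest-weight 10% of the survivors each round

Every ranker yields a full permutation of the genes in descending
relevance (:class:`RankedList`); ties are broken by original gene index
so rankings are reproducible bit-for-bit.  Cutting a list at a threshold
``t`` gives the candidate biomarker signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .datasets import ExpressionDataset, GeneSet
from .discretize import apply_discretization, entropy_bits, mdl_discretize

__all__ = [
    "RANKER_NAMES",
    "RankedList",
    "score_chi2",
    "score_info_gain",
    "score_symmetrical_uncertainty",
    "score_gain_ratio",
    "score_oner",
    "score_relieff",
    "rank_svm_one",
    "rank_svm_rfe",
    "rank_features",
    "cut_ranking",
]

RANKER_NAMES = ("CHI2", "IG", "SU", "GR", "ONER", "RELIEFF", "SVM_ONE", "SVM_RFE")


@dataclass
class RankedList:
    """Genes in descending relevance order with aligned scores."""

    ranker_name: str
    ordered_genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ordered_genes) != len(self.scores):
            raise ValueError("genes and scores must be aligned")

    def cut(self, t: int) -> GeneSet:
        return cut_ranking(self, t)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tscore\n")
            for g, s in zip(self.ordered_genes, self.scores):
                fh.write(f"{g}\t{s!r}\n")


# ---------------------------------------------------------------------------
# contingency-table machinery for the univariate entropic/statistic scorers

def _contingency(bins: np.ndarray, y: np.ndarray) -> np.ndarray:
    """bins×2 contingency counts of discretized gene vs. binary class."""
    n_bins = int(bins.max()) + 1
    table = np.zeros((n_bins, 2))
    np.add.at(table, (bins, y), 1)
    return table


def chi2_statistic(table: np.ndarray) -> float:
    """Pearson χ² of a contingency table; 0 for degenerate margins."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    if n == 0 or (row > 0).sum() < 2 or (col > 0).sum() < 2:
        return 0.0
    expected = row @ col / n
    mask = expected > 0
    return float(((table - expected)[mask] ** 2 / expected[mask]).sum())


def info_gain(table: np.ndarray) -> float:
    """IG = H(C) − H(C|X) in bits from a bins×classes table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        return 0.0
    h_class = _entropy_counts(table.sum(axis=0))
    h_cond = sum(
        row.sum() / n * _entropy_counts(row) for row in table if row.sum() > 0
    )
    return float(h_class - h_cond)


def symmetrical_uncertainty(table: np.ndarray) -> float:
    """SU = 2·IG / (H(C) + H(X)); 0 when both entropies vanish."""
    table = np.asarray(table, dtype=float)
    h_x = _entropy_counts(table.sum(axis=1))
    h_c = _entropy_counts(table.sum(axis=0))
    if h_x + h_c == 0:
        return 0.0
    return float(2.0 * info_gain(table) / (h_x + h_c))


def gain_ratio(table: np.ndarray) -> float:
    """GR = IG / H(X); 0 when the gene is constant (H(X) = 0)."""
    table = np.asarray(table, dtype=float)
    h_x = _entropy_counts(table.sum(axis=1))
    if h_x == 0:
        return 0.0
    return float(info_gain(table) / h_x)


def _entropy_counts(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    if counts.size == 0:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _discretized_tables(dataset: ExpressionDataset):
    y = dataset.y
    for j in range(dataset.n_genes):
        v = dataset.values[:, j]
        cuts = mdl_discretize(v, y)
        yield _contingency(apply_discretization(v, cuts), y)


def score_chi2(dataset: ExpressionDataset) -> np.ndarray:
    """Per-gene Pearson χ² over MDL-discretized bins; single-bin genes score 0."""
    return np.array([chi2_statistic(t) for t in _discretized_tables(dataset)])


def score_info_gain(dataset: ExpressionDataset) -> np.ndarray:
    return np.array([info_gain(t) for t in _discretized_tables(dataset)])


def score_symmetrical_uncertainty(dataset: ExpressionDataset) -> np.ndarray:
    return np.array([symmetrical_uncertainty(t) for t in _discretized_tables(dataset)])


def score_gain_ratio(dataset: ExpressionDataset) -> np.ndarray:
    return np.array([gain_ratio(t) for t in _discretized_tables(dataset)])


# ---------------------------------------------------------------------------
# OneR

def oner_accuracy(values: np.ndarray, y: np.ndarray, min_bucket: int = 6) -> float:
    """Training accuracy (%) of the one-gene bucket rule.

    Instances are sorted by value and grouped into buckets, each closed
    once some class reaches ``min_bucket`` members and the run of equal
    values / same-class instances ends.  Adjacent buckets with the same
    majority class merge.  The rule predicts each bucket's majority class.
    """
    order = np.argsort(values, kind="stable")
    v, c = values[order], y[order]
    n = len(v)
    buckets: list[tuple[int, int]] = []  # (start, end) half-open
    start = 0
    while start < n:
        counts = {0: 0, 1: 0}
        end = start
        majority = None
        while end < n:
            counts[c[end]] += 1
            end += 1
            if majority is None and max(counts.values()) >= min_bucket:
                majority = max(counts, key=lambda k: counts[k])
                # extend through ties in value and the run of majority class
                while end < n and (v[end] == v[end - 1] or c[end] == majority):
                    counts[c[end]] += 1
                    end += 1
                break
        buckets.append((start, end))
        start = end
    # a trailing bucket without a clear majority merges into its predecessor
    if len(buckets) > 1:
        s, e = buckets[-1]
        cnt = np.bincount(c[s:e], minlength=2)
        if cnt.max() < min_bucket:
            buckets[-2] = (buckets[-2][0], e)
            buckets.pop()
    # merge adjacent buckets with equal majority class
    merged: list[tuple[int, int]] = []
    for s, e in buckets:
        maj = int(np.bincount(c[s:e], minlength=2).argmax())
        if merged and merged[-1][2] == maj:
            merged[-1] = (merged[-1][0], e, maj)
        else:
            merged.append((s, e, maj))
    correct = sum(int(np.bincount(c[s:e], minlength=2)[m]) for s, e, m in merged)
    return 100.0 * correct / n


def score_oner(dataset: ExpressionDataset, min_bucket: int = 6) -> np.ndarray:
    y = dataset.y
    return np.array(
        [oner_accuracy(dataset.values[:, j], y, min_bucket) for j in range(dataset.n_genes)]
    )


# ---------------------------------------------------------------------------
# ReliefF

def _minmax(values: np.ndarray) -> np.ndarray:
    lo = values.min(axis=0)
    rng = values.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (values - lo) / rng


def score_relieff(dataset: ExpressionDataset, k_neighbors: int = 10) -> np.ndarray:
    """ReliefF weights over every instance, nearest hits/misses per class.

    Features are min-max scaled to [0, 1]; neighbours are found under the
    Manhattan distance over all genes.  For each instance the weight of
    gene g decreases by the hit differences and increases by the
    prior-weighted miss differences, each averaged over ``m·k`` updates.
    ``k`` is truncated to the neighbours actually available in a class.
    """
    y = dataset.y
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("ReliefF needs at least 2 instances per class")
    x = _minmax(dataset.values)
    z, n = x.shape
    dist = cdist(x, x, metric="cityblock")
    prior = np.bincount(y, minlength=2) / z
    w = np.zeros(n)
    for i in range(z):
        own = y[i]
        for cls in (0, 1):
            idx = np.nonzero(y == cls)[0]
            idx = idx[idx != i]
            k = min(k_neighbors, len(idx))
            if k == 0:
                continue
            nearest = idx[np.argsort(dist[i, idx], kind="stable")[:k]]
            diff = np.abs(x[nearest] - x[i]).sum(axis=0)
            if cls == own:
                w -= diff / (z * k)
            else:
                w += prior[cls] / (1.0 - prior[own]) * diff / (z * k)
    return w


# ---------------------------------------------------------------------------
# SVM-embedded rankers

def _fit_linear_svm(x: np.ndarray, y: np.ndarray, c: float) -> np.ndarray:
    """Squared weight per feature of a linear soft-margin SVM (exact QP)."""
    clf = SVC(kernel="linear", C=c)
    clf.fit(x, y)
    return np.asarray(clf.coef_).ravel() ** 2


def rank_svm_one(dataset: ExpressionDataset, c_parameter: float = 1.0) -> RankedList:
    """Rank genes by descending squared weight of one linear SVM fit."""
    x = _minmax(dataset.values)
    w2 = _fit_linear_svm(x, dataset.y, c_parameter)
    order = np.argsort(-w2, kind="stable")
    return RankedList(
        ranker_name="SVM_ONE",
        ordered_genes=[dataset.gene_ids[j] for j in order],
        scores=w2[order],
    )


def rank_svm_rfe(
    dataset: ExpressionDataset,
    removal_fraction: float = 0.10,
    c_parameter: float = 1.0,
) -> RankedList:
    """SVM recursive feature elimination.

    Each round refits the SVM on the surviving genes and drops the
    ``ceil(removal_fraction · survivors)`` genes of lowest squared weight
    (at least one, never all).  The final ranking is the reverse of the
    elimination order; within a dropped batch genes keep their
    descending-w² order, and the scores column carries the w² each gene
    had in the round it left (so it is non-increasing only within rounds).
    """
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must be in (0, 1)")
    x = _minmax(dataset.values)
    y = dataset.y
    surviving = np.arange(dataset.n_genes)
    ranking: list[tuple[int, float]] = []  # built bottom-up
    while len(surviving) > 1:
        w2 = _fit_linear_svm(x[:, surviving], y, c_parameter)
        n_drop = min(
            max(1, int(np.ceil(removal_fraction * len(surviving)))),
            len(surviving) - 1,
        )
        order = np.argsort(w2, kind="stable")  # ascending: drop the head
        dropped = order[:n_drop]
        # batch enters the ranking above previously dropped genes; the
        # bottom-up list is later reversed, so appending in ascending w²
        # leaves the batch internally ordered by descending w²
        for pos in dropped:
            ranking.append((surviving[pos], float(w2[pos])))
        keep = np.ones(len(surviving), dtype=bool)
        keep[dropped] = False
        surviving = surviving[keep]
    ranking.append((int(surviving[0]), float("inf")))
    ranking.reverse()
    return RankedList(
        ranker_name="SVM_RFE",
        ordered_genes=[dataset.gene_ids[j] for j, _ in ranking],
        scores=np.array([s for _, s in ranking]),
    )


# ---------------------------------------------------------------------------
# dispatch

_SCORERS = {
    "CHI2": score_chi2,
    "IG": score_info_gain,
    "SU": score_symmetrical_uncertainty,
    "GR": score_gain_ratio,
    "ONER": score_oner,
    "RELIEFF": score_relieff,
}


def rank_features(dataset: ExpressionDataset, ranker_name: str) -> RankedList:
    """Produce the full ranked list for one ranker.

    Scores are sorted descending; ties resolve to the gene that appears
    first in the dataset, so the permutation is deterministic.
    """
    name = ranker_name.upper()
    if name == "SVM_ONE":
        return rank_svm_one(dataset)
    if name == "SVM_RFE":
        return rank_svm_rfe(dataset)
    if name not in _SCORERS:
        raise ValueError(f"unknown ranker {ranker_name!r}; valid: {', '.join(RANKER_NAMES)}")
    scores = _SCORERS[name](dataset)
    order = np.argsort(-scores, kind="stable")
    return RankedList(
        ranker_name=name,
        ordered_genes=[dataset.gene_ids[j] for j in order],
        scores=scores[order],
    )


def cut_ranking(ranking: RankedList, t: int) -> GeneSet:
    """The top-``t`` genes of a ranked list as an unordered signature."""
    if not 1 <= t <= len(ranking.ordered_genes):
        raise ValueError(f"t must be in [1, {len(ranking.ordered_genes)}], got {t}")
    return GeneSet(
        genes=frozenset(ranking.ordered_genes[:t]),
        source_ranker=ranking.ranker_name,
        threshold_t=t,
    )
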