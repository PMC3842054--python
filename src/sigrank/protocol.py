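"""Joint stability / predictive-performance evaluation under subsampling.

The protocol draws ``P`` reduced datasets ``D_k`` from the original data
``D`` (a stratified fraction ``f`` of the ``Z`` samples, without
replacement), with the held-out remainder ``T_k`` as test set.  Each
ranker is applied to each ``D_k`` only — test instances never influence
gene selection — giving ranked lists that are cut at each threshold
``t`` into signatures ``S_ik``.  Then, per ranker and threshold:

* **stability** is the average pairwise overlap (Jaccard) of the P
  signatures: a stable ranker selects nearly the same genes under small
  sample perturbations;
* **performance** is the mean AUC, over the P splits, of a linear SVM
  trained on ``D_k`` restricted to ``S_ik`` and scored on ``T_k``.

The public surface follows the model/results idiom:
:class:`RankerComparison` is built from a dataset and protocol settings;
``fit(seed)`` runs the experiment and returns
:class:`RankerComparisonResults` holding per-ranker stability and AUC
profiles, with ``summary()``, tidy/JSON export and curve plotting.
Thin functional wrappers (:func:`evaluate_stability`,
:func:`evaluate_performance`, :func:`joint_evaluation`) cover the
single-ranker use cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

from .datasets import ExpressionDataset
from .rankers import RANKER_NAMES, RankedList, cut_ranking, rank_features
from .setsim import average_offdiagonal, pairwise_similarity_matrix

__all__ = [
    "SubsampleScheme",
    "StabilityProfile",
    "PerformanceProfile",
    "draw_subsamples",
    "train_and_score",
    "auc_from_scores",
    "evaluate_stability",
    "evaluate_performance",
    "joint_evaluation",
    "RankerComparison",
    "RankerComparisonResults",
]


# ---------------------------------------------------------------------------
# subsampling

@dataclass
class SubsampleScheme:
    """P stratified train/test splits of a dataset at train fraction f."""

    p_count: int
    fraction_f: float
    splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    def __iter__(self):
        return iter(self.splits)


def _stratified_train_counts(
    class_sizes: np.ndarray, n_train: int, fraction_f: float
) -> np.ndarray:
    """Per-class ⌊f·n_c⌋ draws, topped up by largest remainder to n_train."""
    quota = fraction_f * class_sizes
    counts = np.floor(quota).astype(int)
    # every class keeps >= 1 train and >= 1 test instance
    counts = np.maximum(counts, 1)
    counts = np.minimum(counts, class_sizes - 1)
    remainder = quota - counts
    order = np.argsort(-remainder, kind="stable")
    i = 0
    while counts.sum() < n_train and i < 10 * len(counts):
        c = order[i % len(counts)]
        if counts[c] < class_sizes[c] - 1:
            counts[c] += 1
        i += 1
    while counts.sum() > n_train:
        c = int(np.argmax(counts - quota))
        counts[c] -= 1
    return counts


def draw_subsamples(
    dataset: ExpressionDataset,
    p_count: int = 20,
    fraction_f: float = 0.9,
    seed: int = 0,
) -> SubsampleScheme:
    """Draw P independent stratified splits with |train| = ⌊f·Z⌋.

    Sampling is without replacement within a split; splits are mutually
    independent (this is repeated subsampling, not cross-validation).
    The master seed expands deterministically to one child seed per
    split, so the scheme is reproducible from (seed, Z, labels).
    """
    if not 0 < fraction_f < 1:
        raise ValueError("fraction_f must be in (0, 1)")
    y = dataset.y
    z = dataset.n_samples
    n_train = int(np.floor(fraction_f * z))
    class_sizes = np.bincount(y, minlength=2)
    if class_sizes.min() < 2:
        neg, pos = dataset.classes
        small = neg if class_sizes[0] < 2 else pos
        raise ValueError(f"class {small!r} too small to stratify (needs >= 2 samples)")
    train_counts = _stratified_train_counts(class_sizes, n_train, fraction_f)
    if np.any(train_counts >= class_sizes) or np.any(train_counts < 1):
        neg, pos = dataset.classes
        bad = [neg, pos][int(np.argmin(class_sizes - train_counts))]
        raise ValueError(f"fraction leaves no test instance for class {bad!r}")
    child_seeds = np.random.SeedSequence(seed).spawn(p_count)
    splits = []
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        train_idx = []
        for cls in (0, 1):
            members = np.nonzero(y == cls)[0]
            chosen = rng.choice(members, size=train_counts[cls], replace=False)
            train_idx.append(chosen)
        train = np.sort(np.concatenate(train_idx))
        test = np.setdiff1d(np.arange(z), train)
        splits.append((train, test))
    return SubsampleScheme(p_count=p_count, fraction_f=fraction_f, splits=splits, seed=seed)


# ---------------------------------------------------------------------------
# profiles

@dataclass
class StabilityProfile:
    """Per-threshold stability (mean pairwise signature overlap across splits)."""

    ranker_name: str
    stability: dict[int, float]
    p_count: int
    fraction_f: float
    seed: int


@dataclass
class PerformanceProfile:
    """Per-threshold held-out AUC (mean and SD over the P splits)."""

    ranker_name: str
    auc_mean: dict[int, float]
    auc_sd: dict[int, float]
    p_count: int
    fraction_f: float
    seed: int


# ---------------------------------------------------------------------------
# classification

def _minmax_fit(train: np.ndarray):
    lo = train.min(axis=0)
    rng = train.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return lo, rng


def train_and_score(
    train: ExpressionDataset,
    test: ExpressionDataset,
    c_parameter: float = 1.0,
) -> np.ndarray:
    """Linear-SVM decision values for the test samples.

    Min-max scaling is fitted on the training data only and applied to
    the test data; values are signed toward the positive class.
    """
    y_train = train.y
    if len(np.unique(y_train)) < 2:
        raise ValueError("degenerate single-class training split")
    lo, rng = _minmax_fit(train.values)
    clf = SVC(kernel="linear", C=c_parameter)
    clf.fit((train.values - lo) / rng, y_train)
    scores = clf.decision_function((test.values - lo) / rng)
    # libsvm orients decision values toward classes_[1]
    return scores if clf.classes_[1] == 1 else -scores


def auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann–Whitney statistic.

    The fraction of (positive, negative) pairs where the positive sample
    outscores the negative one, ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined with a single class")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 credit
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# evaluation core

def _rankings_per_split(
    dataset: ExpressionDataset, ranker_name: str, scheme: SubsampleScheme
) -> list[RankedList]:
    return [
        rank_features(dataset.subset_samples(train), ranker_name)
        for train, _ in scheme
    ]


def _stability_from_rankings(
    rankings: list[RankedList], thresholds: list[int]
) -> dict[int, float]:
    out = {}
    for t in thresholds:
        sets = [cut_ranking(r, t) for r in rankings]
        out[t] = average_offdiagonal(pairwise_similarity_matrix(sets))
    return out


def _performance_from_rankings(
    dataset: ExpressionDataset,
    rankings: list[RankedList],
    scheme: SubsampleScheme,
    thresholds: list[int],
) -> tuple[dict[int, float], dict[int, float]]:
    means, sds = {}, {}
    for t in thresholds:
        aucs = []
        for (train, test), ranking in zip(scheme, rankings):
            genes = cut_ranking(ranking, t)
            d_train = dataset.subset_samples(train).subset_genes(genes)
            d_test = dataset.subset_samples(test).subset_genes(genes)
            scores = train_and_score(d_train, d_test)
            aucs.append(auc_from_scores(scores, d_test.y))
        means[t] = float(np.mean(aucs))
        sds[t] = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    return means, sds


def evaluate_stability(
    dataset: ExpressionDataset,
    ranker_name: str,
    scheme: SubsampleScheme,
    thresholds: list[int],
) -> StabilityProfile:
    """Stability profile of one ranker: rank each D_k, cut at each t, average overlap."""
    rankings = _rankings_per_split(dataset, ranker_name, scheme)
    return StabilityProfile(
        ranker_name=ranker_name,
        stability=_stability_from_rankings(rankings, thresholds),
        p_count=scheme.p_count,
        fraction_f=scheme.fraction_f,
        seed=scheme.seed,
    )


def evaluate_performance(
    dataset: ExpressionDataset,
    ranker_name: str,
    scheme: SubsampleScheme,
    thresholds: list[int],
) -> PerformanceProfile:
    """AUC profile of one ranker over the held-out test sets."""
    rankings = _rankings_per_split(dataset, ranker_name, scheme)
    means, sds = _performance_from_rankings(dataset, rankings, scheme, thresholds)
    return PerformanceProfile(
        ranker_name=ranker_name,
        auc_mean=means,
        auc_sd=sds,
        p_count=scheme.p_count,
        fraction_f=scheme.fraction_f,
        seed=scheme.seed,
    )


def joint_evaluation(
    dataset: ExpressionDataset,
    ranker_names: list[str],
    scheme: SubsampleScheme,
    thresholds: list[int],
) -> dict[str, tuple[StabilityProfile, PerformanceProfile]]:
    """Stability and AUC for several rankers, ranking each D_k once per ranker."""
    out = {}
    for name in ranker_names:
        rankings = _rankings_per_split(dataset, name, scheme)
        stab = _stability_from_rankings(rankings, thresholds)
        means, sds = _performance_from_rankings(dataset, rankings, scheme, thresholds)
        out[name] = (
            StabilityProfile(name, stab, scheme.p_count, scheme.fraction_f, scheme.seed),
            PerformanceProfile(name, means, sds, scheme.p_count, scheme.fraction_f, scheme.seed),
        )
    return out


# ---------------------------------------------------------------------------
# model / results surface

class RankerComparison:
    """Comparative experiment over a set of rankers on one dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
        The full two-class expression study.
    rankers : sequence of str, optional
        Ranker names to compare; defaults to all eight.
    thresholds : sequence of int, optional
        Signature sizes t at which ranked lists are cut (default
        5, 10, 20, 30).
    p_count : int
        Number of reduced datasets (default 20).
    fraction_f : float
        Train fraction per reduced dataset (default 0.9).

    Examples
    --------
    >>> model = RankerComparison(dataset, thresholds=[10])
    >>> res = model.fit(seed=42)
    >>> res.summary()           # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        rankers: list[str] | None = None,
        thresholds: list[int] | None = None,
        p_count: int = 20,
        fraction_f: float = 0.9,
    ):
        self.dataset = dataset
        self.rankers = [r.upper() for r in (rankers or RANKER_NAMES)]
        self.thresholds = sorted(thresholds or [5, 10, 20, 30])
        if self.thresholds[0] < 1 or self.thresholds[-1] > dataset.n_genes:
            raise ValueError(
                f"thresholds must lie in [1, {dataset.n_genes}], got {self.thresholds}"
            )
        self.p_count = p_count
        self.fraction_f = fraction_f

    def fit(self, seed: int = 0) -> "RankerComparisonResults":
        """Run the subsampling protocol and collect all profiles."""
        scheme = draw_subsamples(self.dataset, self.p_count, self.fraction_f, seed)
        profiles = joint_evaluation(self.dataset, self.rankers, scheme, self.thresholds)
        return RankerComparisonResults(model=self, scheme=scheme, profiles=profiles)


@dataclass
class RankerComparisonResults:
    """Fitted ranker-comparison experiment: stability and AUC per ranker and t."""

    model: RankerComparison
    scheme: SubsampleScheme
    profiles: dict[str, tuple[StabilityProfile, PerformanceProfile]]
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def stability_(self) -> pd.DataFrame:
        """Rankers × thresholds stability table."""
        return pd.DataFrame(
            {t: {r: p[0].stability[t] for r, p in self.profiles.items()}
             for t in self.model.thresholds}
        )

    @property
    def auc_mean_(self) -> pd.DataFrame:
        return pd.DataFrame(
            {t: {r: p[1].auc_mean[t] for r, p in self.profiles.items()}
             for t in self.model.thresholds}
        )

    @property
    def auc_sd_(self) -> pd.DataFrame:
        return pd.DataFrame(
            {t: {r: p[1].auc_sd[t] for r, p in self.profiles.items()}
             for t in self.model.thresholds}
        )

    def to_tidy(self) -> pd.DataFrame:
        """Long-form table: ranker, t, metric, value."""
        rows = []
        for r, (stab, perf) in self.profiles.items():
            for t in self.model.thresholds:
                rows.append((r, t, "stability", stab.stability[t]))
                rows.append((r, t, "auc_mean", perf.auc_mean[t]))
                rows.append((r, t, "auc_sd", perf.auc_sd[t]))
        return pd.DataFrame(rows, columns=["ranker", "t", "metric", "value"])

    def to_dict(self) -> dict:
        return {
            "p_count": self.scheme.p_count,
            "fraction_f": self.scheme.fraction_f,
            "seed": self.scheme.seed,
            "thresholds": list(self.model.thresholds),
            "stability": {r: {str(t): v for t, v in p[0].stability.items()}
                          for r, p in self.profiles.items()},
            "auc_mean": {r: {str(t): v for t, v in p[1].auc_mean.items()}
                         for r, p in self.profiles.items()},
            "auc_sd": {r: {str(t): v for t, v in p[1].auc_sd.items()}
                       for r, p in self.profiles.items()},
        }

    def summary(self) -> str:
        """Human-readable stability / AUC table across rankers and thresholds."""
        lines = [
            "Ranker comparison under subsampling",
            f"  Z = {self.model.dataset.n_samples} samples, "
            f"N = {self.model.dataset.n_genes} genes",
            f"  P = {self.scheme.p_count} reduced datasets, "
            f"f = {self.scheme.fraction_f}, seed = {self.scheme.seed}",
            "",
            f"{'ranker':<10}" + "".join(
                f"  stab@{t:<4} auc@{t:<6}" for t in self.model.thresholds
            ),
        ]
        for r in self.model.rankers:
            stab, perf = self.profiles[r]
            cells = "".join(
                f"  {stab.stability[t]:>8.3f} {perf.auc_mean[t]:>6.3f}"
                + " " * max(0, len(f" auc@{t:<6}") - 7)
                for t in self.model.thresholds
            )
            lines.append(f"{r:<10}{cells}")
        return "\n".join(lines)

    def plot_stability(self, ax=None):
        """Stability-vs-signature-size curves, one line per ranker."""
        return self._plot("stability", "Stability (avg pairwise overlap)", ax)

    def plot_auc(self, ax=None):
        """Held-out AUC-vs-signature-size curves, one line per ranker."""
        return self._plot("auc_mean", "Mean held-out AUC", ax)

    def _plot(self, metric: str, ylabel: str, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.stability_ if metric == "stability" else self.auc_mean_
        for r in frame.index:
            ax.plot(frame.columns, frame.loc[r], marker="o", label=r)
        ax.set_xlabel("number of selected genes (t)")
        ax.set_ylabel(ylabel)
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
        return ax
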