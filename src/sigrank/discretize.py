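"""Supervised discretization by recursive entropy minimisation (Fayyad–Irani).

The univariate scorers (χ², information gain, symmetrical uncertainty,
gain ratio) are defined on discrete variables, so each continuous gene is
first binned against the class labels.  A candidate cut is the midpoint
between two adjacent distinct values; the cut maximising information gain
is accepted iff the gain exceeds the minimum-description-length cost

    gain > ( log2(n-1) + log2(3^k - 2) - [k*H(S) - k1*H(S1) - k2*H(S2)] ) / n

where ``k``, ``k1``, ``k2`` are the class counts present in the node and
its two halves.  Accepted halves are split recursively.  A gene on which
no cut is accepted collapses to a single bin (and will score zero under
every univariate criterion).

Bins are left-open/right-closed: value ``v`` falls in bin ``i`` iff
``cuts[i-1] < v <= cuts[i]``, so a value exactly at a cut goes to the
lower bin.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mdl_discretize", "apply_discretization", "entropy_bits"]


def entropy_bits(labels: np.ndarray) -> float:
    """Shannon entropy (base 2) of a label vector; 0·log0 = 0."""
    if len(labels) == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    """Row-wise entropy (bits) of count matrices; rows summing to 0 give 0."""
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


def _best_cut(values: np.ndarray, onehot: np.ndarray):
    """Best midpoint cut by information gain, or None if no candidate.

    ``values`` must be sorted ascending, ``onehot`` the aligned Z×k class
    indicator matrix.  Ties in value admit no cut between them, so
    candidates sit only between distinct adjacent values.  Candidate
    entropies are evaluated in one vectorised pass; ties on gain resolve
    to the lowest cut.
    """
    n = len(values)
    distinct = np.nonzero(np.diff(values) > 0)[0]  # cut after position i
    if distinct.size == 0:
        return None
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    left = cum[distinct]
    right = total - left
    n_left = distinct + 1
    h_total = float(_entropy_from_counts(total))
    h_left = _entropy_from_counts(left)
    h_right = _entropy_from_counts(right)
    gain = h_total - (n_left * h_left + (n - n_left) * h_right) / n
    b = int(np.argmax(gain))  # argmax takes the first (lowest cut) on ties
    i = distinct[b]
    cut = (values[i] + values[i + 1]) / 2.0
    k = int((total > 0).sum())
    k1 = int((left[b] > 0).sum())
    k2 = int((right[b] > 0).sum())
    delta = np.log2(3.0**k - 2.0) - (k * h_total - k1 * h_left[b] - k2 * h_right[b])
    threshold = (np.log2(n - 1) + delta) / n
    return float(cut), float(gain[b]), int(n_left[b]), float(threshold)


def _recurse(values: np.ndarray, onehot: np.ndarray, cuts: list[float]) -> None:
    found = _best_cut(values, onehot)
    if found is None:
        return
    cut, gain, n_left, threshold = found
    if gain <= 0 or gain <= threshold:
        return
    cuts.append(cut)
    _recurse(values[:n_left], onehot[:n_left], cuts)
    _recurse(values[n_left:], onehot[n_left:], cuts)


def mdl_discretize(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Cut thresholds for one gene, ascending (possibly empty).

    Parameters
    ----------
    values : array of shape (Z,)
        Continuous expression levels, Z >= 2.
    labels : array of shape (Z,)
        Class label per sample (any hashable symbols).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must be aligned")
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    order = np.argsort(values, kind="stable")
    _, inverse = np.unique(labels, return_inverse=True)
    onehot = np.eye(int(inverse.max()) + 1, dtype=np.int64)[inverse]
    cuts: list[float] = []
    _recurse(values[order], onehot[order], cuts)
    return sorted(cuts)


def apply_discretization(values: np.ndarray, cuts: list[float]) -> np.ndarray:
    """Map values to bin indices in ``[0, len(cuts)]`` (value at a cut → lower bin)."""
    return np.searchsorted(np.asarray(cuts, dtype=float), np.asarray(values, dtype=float), side="left")
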