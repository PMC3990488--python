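"""RDM comparison by correlation coefficients, including Kendall's tau-a.

tau-a is the proportion of pairs of values that are consistently ordered in
both variables: ``(concordant - discordant) / (n (n - 1) / 2)``.  Pairs tied
in either vector count in the denominator but in neither tally, which makes
tau-a the appropriate coefficient when candidate models predict tied
dissimilarities.  Two implementations are provided: an O(n^2) enumeration
(:func:`kendall_tau_a_reference`) kept as an independent oracle, and an
O(n log n) merge-sort variant (:func:`kendall_tau_a`) used in production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .rdm import RDM, RDMCollection

__all__ = [
    "kendall_tau_a",
    "kendall_tau_a_reference",
    "compare_rdms",
    "rdm_correlation_matrix",
    "RDMComparisonMatrix",
    "COMPARISON_METHODS",
]

COMPARISON_METHODS = ("pearson", "spearman", "kendall_tau_a")


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 values")
    return a, b


def _tie_pairs(x: np.ndarray) -> int:
    """Number of pairs tied within ``x``."""
    _, counts = np.unique(x, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def _count_inversions(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Sorted copy of ``x`` and the number of strict inversions (i<j, x_i>x_j)."""
    n = x.size
    if n < 2:
        return x, 0
    mid = n // 2
    left, c_left = _count_inversions(x[:mid])
    right, c_right = _count_inversions(x[mid:])
    # for each right element, count left elements strictly greater
    cross = int(np.sum(left.size - np.searchsorted(left, right, side="right")))
    return np.sort(np.concatenate([left, right]), kind="mergesort"), c_left + c_right + cross


def kendall_tau_a(a, b) -> float:
    """Kendall's tau-a via merge-sort inversion counting, O(n log n).

    Ties in either input reduce the numerator but never the denominator.
    """
    a, b = _check_pair(a, b)
    n = a.size
    n0 = n * (n - 1) // 2
    order = np.lexsort((b, a))
    b_sorted = b[order]
    # after sorting by (a, b), strict inversions of b are exactly the
    # discordant pairs: within a tied-a group b is ascending (0 inversions,
    # and those pairs are neither concordant nor discordant)
    _, discordant = _count_inversions(b_sorted)
    n1 = _tie_pairs(a)
    n2 = _tie_pairs(b)
    joint = np.unique(np.column_stack([a, b]), axis=0, return_counts=True)[1]
    n3 = int(np.sum(joint * (joint - 1) // 2))
    concordant = n0 - n1 - n2 + n3 - discordant
    return (concordant - discordant) / n0


def kendall_tau_a_reference(a, b) -> float:
    """Brute-force tau-a by full pair enumeration, O(n^2) (test oracle)."""
    a, b = _check_pair(a, b)
    n = a.size
    sa = np.sign(a[:, None] - a[None, :])
    sb = np.sign(b[:, None] - b[None, :])
    iu = np.triu_indices(n, k=1)
    prod = sa[iu] * sb[iu]
    concordant = int(np.sum(prod > 0))
    discordant = int(np.sum(prod < 0))
    return (concordant - discordant) / iu[0].size


def compare_vectors(a, b, method: str) -> float:
    """Correlation coefficient of the chosen type between two vectors."""
    a, b = _check_pair(a, b)
    if method == "kendall_tau_a":
        return float(kendall_tau_a(a, b))
    if method not in COMPARISON_METHODS:
        raise ValueError(
            f"method must be one of {COMPARISON_METHODS}, got {method!r}"
        )
    for name, v in (("first", a), ("second", b)):
        if np.ptp(v) == 0:
            raise ValueError(
                f"{method} correlation undefined: {name} vector is constant"
            )
    if method == "pearson":
        return float(pearsonr(a, b).statistic)
    return float(spearmanr(a, b).statistic)


def compare_rdms(rdm1: RDM, rdm2: RDM, method: str = "kendall_tau_a") -> float:
    """Compare two RDMs on their vectorized upper triangles only.

    Diagonals and lower triangles are never compared (they would double
    count every dissimilarity).
    """
    if rdm1.condition_labels != rdm2.condition_labels:
        raise ValueError(
            f"RDMs {rdm1.name!r} and {rdm2.name!r} have different condition sets"
        )
    try:
        return compare_vectors(rdm1.dissimilarities, rdm2.dissimilarities, method)
    except ValueError as err:
        raise ValueError(
            f"comparing {rdm1.name!r} with {rdm2.name!r}: {err}"
        ) from err


@dataclass(frozen=True)
class RDMComparisonMatrix:
    """Pairwise RDM correlation matrix, symmetric about a diagonal of ones."""

    labels: tuple[str, ...]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match number of labels")
        object.__setattr__(self, "values", values)


def rdm_correlation_matrix(
    collection: RDMCollection, method: str = "kendall_tau_a"
) -> RDMComparisonMatrix:
    """All pairwise RDM correlations within a collection."""
    if len(collection) < 2:
        raise ValueError("need at least 2 RDMs to build a comparison matrix")
    m = len(collection)
    values = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = compare_rdms(
                collection[i], collection[j], method
            )
    return RDMComparisonMatrix(labels=collection.names, values=values, method=method)
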