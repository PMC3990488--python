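"""Core data structures for representational similarity analysis.

The central exchange object is the :class:`RDM` — a symmetric, zero-diagonal
matrix of pairwise dissimilarities between condition-evoked activity
patterns, stored in vectorized form.  The canonical vector layout throughout
the package is the **upper triangle in row-major order, diagonal excluded**
(the same convention as :func:`scipy.spatial.distance.squareform`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

__all__ = [
    "PatternSet",
    "RDM",
    "RDMCollection",
    "compute_rdm",
    "vectorize",
    "squareform",
    "transform_rdms",
    "transform_vector",
    "average_rdms",
    "n_pairs",
    "MEASURES",
    "TRANSFORMS",
    "ROLES",
]

#: Dissimilarity measure tags an RDM may carry.
MEASURES = ("correlation", "euclidean", "mahalanobis", "ld_t", "model", "other")

#: Measures computable from activity patterns by :func:`compute_rdm`.
PATTERN_MEASURES = ("correlation", "euclidean", "mahalanobis")

#: Entrywise transforms understood by :func:`transform_rdms`.
TRANSFORMS = ("none", "rank", "z", "percentile")

#: Roles an RDM may play inside a collection.
ROLES = ("subject_estimate", "candidate", "reference")

#: Relative symmetry tolerance accepted when vectorizing square matrices.
SYMMETRY_RTOL = 1e-8


def n_pairs(n_conditions: int) -> int:
    """Number of unordered condition pairs, ``n (n - 1) / 2``."""
    return n_conditions * (n_conditions - 1) // 2


def _as_labels(labels: Iterable) -> tuple[str, ...]:
    out = tuple(str(lab) for lab in labels)
    if len(set(out)) != len(out):
        raise ValueError("condition labels must be unique")
    return out


@dataclass(frozen=True)
class PatternSet:
    """Condition x channel activity estimates for one subject or partition.

    Parameters
    ----------
    condition_labels
        Ordered identifiers of the N experimental conditions.
    data
        N x P matrix of activity estimates (arbitrary response units).
    name
        Optional identifier used in error messages and provenance logs.
    """

    condition_labels: tuple[str, ...]
    data: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition_labels", _as_labels(self.condition_labels))
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"pattern data must be 2-D, got shape {data.shape}")
        n, p = data.shape
        if n < 2:
            raise ValueError(f"need at least 2 conditions, got {n}")
        if p < 1:
            raise ValueError("need at least 1 channel")
        if n != len(self.condition_labels):
            raise ValueError(
                f"{len(self.condition_labels)} labels but {n} pattern rows"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("pattern data contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def n_conditions(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class RDM:
    """A representational dissimilarity matrix in vectorized form.

    ``dissimilarities`` holds the upper triangle (row-major, diagonal
    excluded) of the square matrix; use :attr:`matrix` for the square view.
    """

    condition_labels: tuple[str, ...]
    dissimilarities: np.ndarray
    measure: str = "other"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition_labels", _as_labels(self.condition_labels))
        vec = np.asarray(self.dissimilarities, dtype=float).ravel()
        n = len(self.condition_labels)
        if n < 2:
            raise ValueError("an RDM needs at least 2 conditions")
        if vec.size != n_pairs(n):
            raise ValueError(
                f"dissimilarity vector has length {vec.size}, expected "
                f"{n_pairs(n)} for {n} conditions"
            )
        if not np.all(np.isfinite(vec)):
            raise ValueError("dissimilarities contain non-finite values")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; use one of {MEASURES}")
        if self.measure in PATTERN_MEASURES:
            if np.any(vec < -1e-10):
                raise ValueError(
                    f"{self.measure} dissimilarities must be non-negative"
                )
            vec = np.maximum(vec, 0.0)
        object.__setattr__(self, "dissimilarities", vec)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    @property
    def n_pairs(self) -> int:
        return self.dissimilarities.size

    @property
    def matrix(self) -> np.ndarray:
        """Square symmetric matrix view with zero diagonal."""
        return squareform(self.dissimilarities)

    @classmethod
    def from_square(
        cls,
        square: np.ndarray,
        condition_labels: Iterable,
        measure: str = "other",
        name: str = "",
        rtol: float = SYMMETRY_RTOL,
    ) -> "RDM":
        return cls(
            condition_labels=tuple(condition_labels),
            dissimilarities=vectorize(square, rtol=rtol),
            measure=measure,
            name=name,
        )

    def with_dissimilarities(self, vec: np.ndarray, **kwargs) -> "RDM":
        return replace(self, dissimilarities=np.asarray(vec, float), **kwargs)


def vectorize(rdm_square: np.ndarray, rtol: float = SYMMETRY_RTOL) -> np.ndarray:
    """Extract the canonical upper-triangle vector from a square RDM.

    The input must be symmetric with a zero diagonal within ``rtol``
    (relative to the matrix scale).
    """
    m = np.asarray(rdm_square, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    scale = max(float(np.max(np.abs(m))), 1.0)
    if np.max(np.abs(m - m.T)) > rtol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    if np.max(np.abs(np.diag(m))) > rtol * scale:
        raise ValueError("matrix diagonal is not zero within tolerance")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def squareform(vector: np.ndarray, labels: Optional[Sequence] = None) -> np.ndarray:
    """Inverse of :func:`vectorize`: rebuild the square symmetric matrix.

    ``labels``, if given, only validates the expected dimension.
    """
    vec = np.asarray(vector, dtype=float).ravel()
    # solve m = n(n-1)/2 for n
    n = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n_pairs(n) != vec.size:
        raise ValueError(f"vector of length {vec.size} is not a valid triangle")
    if labels is not None and len(labels) != n:
        raise ValueError(f"{len(labels)} labels inconsistent with vector length {vec.size}")
    out = np.zeros((n, n), dtype=float)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out += out.T
    return out


@dataclass(frozen=True)
class RDMCollection:
    """An aligned stack of RDMs sharing one condition set.

    ``roles`` tags each member as a subject estimate, a candidate model, or
    the reference to be explained.
    """

    rdms: tuple[RDM, ...]
    roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        rdms = tuple(self.rdms)
        if not rdms:
            raise ValueError("collection must contain at least one RDM")
        labels = rdms[0].condition_labels
        for r in rdms[1:]:
            if r.condition_labels != labels:
                raise ValueError(
                    f"RDM {r.name!r} has condition labels differing from "
                    f"{rdms[0].name!r}; collections must share one condition set"
                )
        roles = tuple(self.roles) or ("subject_estimate",) * len(rdms)
        if len(roles) != len(rdms):
            raise ValueError("one role per RDM required")
        for role in roles:
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}; use one of {ROLES}")
        object.__setattr__(self, "rdms", rdms)
        object.__setattr__(self, "roles", roles)

    def __len__(self) -> int:
        return len(self.rdms)

    def __iter__(self):
        return iter(self.rdms)

    def __getitem__(self, i: int) -> RDM:
        return self.rdms[i]

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return self.rdms[0].condition_labels

    @property
    def n_conditions(self) -> int:
        return self.rdms[0].n_conditions

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name or f"rdm{i}" for i, r in enumerate(self.rdms))

    def stack(self) -> np.ndarray:
        """(n_rdms, n_pairs) array of dissimilarity vectors."""
        return np.stack([r.dissimilarities for r in self.rdms])


def _regularized_covariance(cov: np.ndarray, regularization) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("noise covariance must be a square matrix")
    if regularization is None:
        return cov
    if regularization == "auto":
        mean_diag = float(np.mean(np.diag(cov)))
        lam = 1e-6 * mean_diag if mean_diag > 0 else 1e-8
    else:
        lam = float(regularization)
    return cov + lam * np.eye(cov.shape[0])


def compute_rdm(
    patterns: PatternSet,
    measure: str = "correlation",
    noise_covariance: Optional[np.ndarray] = None,
    regularization=None,
    name: str = "",
) -> RDM:
    """Compute an RDM from activity patterns.

    Parameters
    ----------
    measure
        ``"correlation"`` (1 minus Pearson correlation across channels),
        ``"euclidean"`` (root-sum-of-squares of the pattern difference), or
        ``"mahalanobis"`` (Euclidean after whitening by the inverse of
        ``noise_covariance``).
    noise_covariance
        P x P noise covariance, required for the Mahalanobis measure.
    regularization
        Optional diagonal loading for the Mahalanobis covariance: ``None``
        (raise on a singular covariance), ``"auto"`` (small fraction of the
        mean diagonal), or an explicit non-negative float.
    """
    if measure not in PATTERN_MEASURES:
        raise ValueError(
            f"measure must be one of {PATTERN_MEASURES}, got {measure!r}"
        )
    data = patterns.data
    if measure == "correlation":
        stds = data.std(axis=1)
        bad = np.flatnonzero(stds == 0)
        if bad.size:
            raise ValueError(
                "correlation distance undefined for zero-variance pattern(s): "
                + ", ".join(patterns.condition_labels[i] for i in bad)
            )
        vec = pdist(data, metric="correlation")
        # pdist can produce tiny negative values from rounding
        vec = np.clip(vec, 0.0, None)
    elif measure == "euclidean":
        vec = pdist(data, metric="euclidean")
    else:  # mahalanobis
        if noise_covariance is None:
            raise ValueError("mahalanobis measure requires a noise_covariance")
        cov = _regularized_covariance(noise_covariance, regularization)
        if cov.shape[0] != patterns.n_channels:
            raise ValueError(
                f"noise covariance is {cov.shape[0]}x{cov.shape[1]} but "
                f"patterns have {patterns.n_channels} channels"
            )
        try:
            chol = cholesky(cov, lower=True)
        except LinAlgError as err:
            raise ValueError(
                "noise covariance is singular; pass regularization='auto' "
                "or an explicit diagonal-loading value"
            ) from err
        whitened = solve_triangular(chol, data.T, lower=True).T
        vec = pdist(whitened, metric="euclidean")
    return RDM(
        condition_labels=patterns.condition_labels,
        dissimilarities=vec,
        measure=measure,
        name=name or patterns.name,
    )


def transform_vector(vec: np.ndarray, transform: str, name: str = "") -> np.ndarray:
    """Apply an entrywise transform to one dissimilarity vector."""
    vec = np.asarray(vec, dtype=float).ravel()
    if transform == "none":
        return vec.copy()
    if transform == "rank":
        return rankdata(vec)  # midranks for ties
    if transform == "z":
        sd = vec.std()
        if sd == 0:
            raise ValueError(
                f"z-transform undefined for constant RDM {name or '<unnamed>'}"
            )
        return (vec - vec.mean()) / sd
    if transform == "percentile":
        return 100.0 * rankdata(vec) / vec.size
    raise ValueError(f"unknown transform {transform!r}; use one of {TRANSFORMS}")


def transform_rdms(collection: RDMCollection, transform: str) -> RDMCollection:
    """Transform every member RDM (rank / z / percentile) of a collection."""
    rdms = tuple(
        r.with_dissimilarities(
            transform_vector(r.dissimilarities, transform, name=r.name or f"#{i}"),
            measure="other" if transform != "none" else r.measure,
        )
        for i, r in enumerate(collection.rdms)
    )
    return RDMCollection(rdms=rdms, roles=collection.roles)


def average_rdms(collection: RDMCollection, transform: str = "none") -> RDM:
    """Entrywise mean RDM after an optional transform.

    For z- (Pearson) and rank- (Spearman) transformed RDMs the mean is the
    RDM minimizing the average squared Euclidean distance to the members,
    i.e. the one maximizing the group-average correlation.
    """
    transformed = transform_rdms(collection, transform)
    mean_vec = transformed.stack().mean(axis=0)
    measures = {r.measure for r in collection.rdms}
    measure = measures.pop() if len(measures) == 1 and transform == "none" else "other"
    return RDM(
        condition_labels=collection.condition_labels,
        dissimilarities=mean_vec,
        measure=measure,
        name="average",
    )
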