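"""The linear-discriminant t (LD-t): crossvalidated pattern separability.

For each condition pair, a Fisher linear discriminant ``w = Sigma^-1 (p1 -
p2)`` is fit on one data partition; the other partition's condition
contrast and residuals are projected onto ``w`` and the t value of the
projected contrast is computed.  The LD-t is symmetrically distributed
around 0 (Student t) when the true pattern distance is 0, so it supports
direct per-pair inference, and it can be read as a crossvalidated,
noise-normalized variation on the Mahalanobis distance.  It is not a
distance in the mathematical sense: it can be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .rdm import RDM, PatternSet

__all__ = [
    "Partition",
    "PartitionedData",
    "LDTResult",
    "pooled_error_covariance",
    "fit_discriminant",
    "ld_t",
    "ldt_rdm",
]

#: Forced diagonal-loading fraction when the residual count cannot support
#: a full-rank covariance estimate.
_FORCED_LOADING_FRACTION = 0.01


def pooled_error_covariance(
    residuals: np.ndarray, regularization: Optional[float] = None
) -> np.ndarray:
    """Error covariance pooled over all stimuli from a T x P residual matrix.

    When ``T <= P`` the sample covariance is singular by construction; in
    that case (without an explicit ``regularization``) diagonal loading with
    a small fraction of the mean diagonal is forced, with a warning.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim != 2:
        raise ValueError(f"residuals must be T x P, got shape {r.shape}")
    t, p = r.shape
    if t <= 1:
        raise ValueError(f"need more than one residual row, got {t}")
    cov = np.cov(r, rowvar=False)
    cov = np.atleast_2d(cov)
    lam = regularization
    if t <= p and lam is None:
        lam = _FORCED_LOADING_FRACTION * float(np.mean(np.diag(cov)))
        if lam == 0.0:
            lam = 1e-8
        warnings.warn(
            f"only {t} residual rows for {p} channels: covariance is rank "
            f"deficient; forcing diagonal loading {lam:.3g}",
            stacklevel=2,
        )
    if lam is not None:
        cov = cov + float(lam) * np.eye(p)
    return cov


def fit_discriminant(
    p1: np.ndarray,
    p2: np.ndarray,
    sigma: np.ndarray,
    regularization: Optional[float] = None,
) -> np.ndarray:
    """Fisher linear discriminant weights ``w = Sigma^-1 (p1 - p2)``."""
    p1 = np.asarray(p1, float).ravel()
    p2 = np.asarray(p2, float).ravel()
    sigma = np.asarray(sigma, float)
    if p1.shape != p2.shape:
        raise ValueError("pattern vectors must have equal length")
    if sigma.shape != (p1.size, p1.size):
        raise ValueError("covariance shape must match pattern length")
    if regularization is not None:
        if regularization == "auto":
            md = float(np.mean(np.diag(sigma)))
            regularization = 1e-6 * md if md > 0 else 1e-8
        sigma = sigma + float(regularization) * np.eye(p1.size)
    try:
        factor = cho_factor(sigma)
    except LinAlgError as err:
        raise ValueError(
            "error covariance is singular; pass a regularization value"
        ) from err
    return cho_solve(factor, p1 - p2)


@dataclass(frozen=True)
class Partition:
    """One independent data partition: condition estimates plus residuals.

    ``dof`` is the residual degrees of freedom (GLM: timepoints minus
    design columns; defaults to T - N).  ``xtx_inv`` is the inverse design
    Gram matrix used to scale contrast variances; when absent, condition
    estimates are treated as unit-variance (contrast variance factor 2).
    """

    patterns: PatternSet
    residuals: np.ndarray
    dof: Optional[int] = None
    xtx_inv: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        residuals = np.asarray(self.residuals, dtype=float)
        if residuals.ndim != 2 or residuals.shape[1] != self.patterns.n_channels:
            raise ValueError(
                f"residuals must be T x {self.patterns.n_channels}, "
                f"got shape {residuals.shape}"
            )
        object.__setattr__(self, "residuals", residuals)
        dof = self.dof
        if dof is None:
            dof = residuals.shape[0] - self.patterns.n_conditions
        if dof < 1:
            raise ValueError(f"residual degrees of freedom must be >= 1, got {dof}")
        object.__setattr__(self, "dof", int(dof))
        if self.xtx_inv is not None:
            x = np.asarray(self.xtx_inv, dtype=float)
            n = self.patterns.n_conditions
            if x.shape != (n, n):
                raise ValueError("xtx_inv must be n_conditions x n_conditions")
            object.__setattr__(self, "xtx_inv", x)

    def contrast_variance_factor(self, i: int, j: int) -> float:
        if self.xtx_inv is None:
            return 2.0
        return float(self.xtx_inv[i, i] + self.xtx_inv[j, j] - 2 * self.xtx_inv[i, j])


@dataclass(frozen=True)
class PartitionedData:
    """Two independent partitions (disjoint runs/sessions) of one dataset."""

    partition1: Partition
    partition2: Partition
    regularization: Optional[float] = None

    def __post_init__(self) -> None:
        a, b = self.partition1.patterns, self.partition2.patterns
        if a.condition_labels != b.condition_labels:
            raise ValueError("partitions must share condition labels")
        if a.n_channels != b.n_channels:
            raise ValueError("partitions must share the channel count")

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return self.partition1.patterns.condition_labels

    @property
    def swapped(self) -> "PartitionedData":
        return PartitionedData(
            partition1=self.partition2,
            partition2=self.partition1,
            regularization=self.regularization,
        )

    @classmethod
    def from_glm(
        cls,
        y1: np.ndarray,
        x1: np.ndarray,
        y2: np.ndarray,
        x2: np.ndarray,
        condition_labels,
        regularization: Optional[float] = None,
    ) -> "PartitionedData":
        """Build partitions by ordinary least squares on two runs."""

        def fit(y, x):
            y = np.asarray(y, float)
            x = np.asarray(x, float)
            beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
            if rank < x.shape[1]:
                raise ValueError("design matrix is rank deficient")
            resid = y - x @ beta
            xtx_inv = np.linalg.inv(x.T @ x)
            return Partition(
                patterns=PatternSet(tuple(condition_labels), beta),
                residuals=resid,
                dof=y.shape[0] - x.shape[1],
                xtx_inv=xtx_inv,
            )

        return cls(fit(y1, x1), fit(y2, x2), regularization=regularization)


@dataclass(frozen=True)
class LDTResult:
    """Signed discriminability in t units for one condition pair."""

    t_value: float
    dof: int
    pair: tuple[str, str]


def ld_t(
    data: PartitionedData,
    pair: tuple[str, str],
    _sigma1: Optional[np.ndarray] = None,
) -> LDTResult:
    """LD-t for one condition pair: fit on partition 1, test on partition 2.

    The t value is positive when the partition-2 contrast agrees in
    direction with the discriminant fit on partition 1.
    """
    labels = data.condition_labels
    try:
        i, j = labels.index(pair[0]), labels.index(pair[1])
    except ValueError as err:
        raise ValueError(f"unknown condition in pair {pair!r}") from err
    part1, part2 = data.partition1, data.partition2
    sigma1 = (
        _sigma1
        if _sigma1 is not None
        else pooled_error_covariance(part1.residuals, data.regularization)
    )
    w = fit_discriminant(
        part1.patterns.data[i],
        part1.patterns.data[j],
        sigma1,
        regularization="auto" if data.regularization is None else data.regularization,
    )
    contrast = float((part2.patterns.data[i] - part2.patterns.data[j]) @ w)
    proj_resid = part2.residuals @ w
    dof = part2.dof
    sigma2_proj = float(proj_resid @ proj_resid) / dof
    if sigma2_proj == 0.0:
        raise ValueError(f"zero projected residual variance for pair {pair!r}")
    se = np.sqrt(sigma2_proj * part2.contrast_variance_factor(i, j))
    return LDTResult(t_value=contrast / se, dof=dof, pair=(labels[i], labels[j]))


def ldt_rdm(data: PartitionedData) -> RDM:
    """Full LD-t RDM: per pair, the mean of the two fold directions.

    Fold 1 fits the discriminant on partition 1 and tests on partition 2;
    fold 2 swaps the roles.  Entries may be negative.
    """
    labels = data.condition_labels
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 conditions")
    swapped = data.swapped
    sigma1 = pooled_error_covariance(data.partition1.residuals, data.regularization)
    sigma2 = pooled_error_covariance(data.partition2.residuals, data.regularization)
    values = []
    for i in range(n):
        for j in range(i + 1, n):
            pair = (labels[i], labels[j])
            try:
                fwd = ld_t(data, pair, _sigma1=sigma1)
                rev = ld_t(swapped, pair, _sigma1=sigma2)
            except ValueError as err:
                raise ValueError(f"LD-t failed for pair {pair!r}: {err}") from err
            values.append(0.5 * (fwd.t_value + rev.t_value))
    return RDM(
        condition_labels=labels,
        dissimilarities=np.array(values),
        measure="ld_t",
        name="ld_t",
    )
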