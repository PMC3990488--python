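"""Noise-ceiling estimation for group-level RDM model comparison.

The ceiling brackets the group-average correlation the unknown true model
could achieve given inter-subject variability: the upper bound is the
average correlation of the (overfitted) central RDM with the single-subject
RDMs; the lower bound is the leave-one-subject-out analogue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .compare import COMPARISON_METHODS, compare_vectors
from .rdm import RDMCollection, transform_vector

__all__ = ["NoiseCeiling", "estimate_noise_ceiling"]

logger = logging.getLogger(__name__)

#: Central-RDM transform per correlation type: after z (Pearson) or rank
#: (Spearman / tau-a) transformation the squared Euclidean distance is
#: proportional to the correlation distance, so the plain mean maximizes
#: the group-average correlation.
_CENTRAL_TRANSFORM = {"pearson": "z", "spearman": "rank", "kendall_tau_a": "rank"}


@dataclass(frozen=True)
class NoiseCeiling:
    """Upper/lower bounds on the attainable group-average RDM correlation."""

    lower: float
    upper: float
    method: str
    n_subjects: int

    def __contains__(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _mean_corr(central: np.ndarray, subjects: np.ndarray, method: str) -> float:
    return float(
        np.mean([compare_vectors(central, s, method) for s in subjects])
    )


def _refine_tau_a_central(
    central: np.ndarray,
    subjects: np.ndarray,
    tol: float = 1e-6,
    max_sweeps: int = 100,
) -> np.ndarray:
    """Greedy coordinate-wise refinement of the tau-a central RDM.

    Starting from the mean of the rank-transformed subject RDMs, each
    coordinate is tentatively snapped to the values of its rank neighbours
    (creating ties); a move is kept when the mean tau-a across subjects
    improves.  Any monotone-improving procedure from this initialization is
    acceptable; the result is an approximate maximizer.
    """
    best = central.copy()
    best_score = _mean_corr(best, subjects, "kendall_tau_a")
    m = best.size
    for _ in range(max_sweeps):
        improved = False
        order = np.argsort(best)
        for pos in range(m):
            k = order[pos]
            candidates = []
            if pos > 0:
                candidates.append(best[order[pos - 1]])
            if pos < m - 1:
                candidates.append(best[order[pos + 1]])
            for value in candidates:
                if value == best[k]:
                    continue
                trial = best.copy()
                trial[k] = value
                score = _mean_corr(trial, subjects, "kendall_tau_a")
                if score > best_score + tol:
                    best, best_score = trial, score
                    improved = True
        if not improved:
            break
    return best


def estimate_noise_ceiling(
    subject_rdms: RDMCollection,
    method: str = "kendall_tau_a",
    refine_max_pairs: int = 150,
    refine_tol: float = 1e-6,
    refine_max_sweeps: int = 100,
) -> NoiseCeiling:
    """Estimate the noise ceiling from single-subject RDM estimates.

    Parameters
    ----------
    subject_rdms
        One reference-RDM estimate per subject (>= 2 subjects).
    method
        Correlation type; determines the central-RDM transform.
    refine_max_pairs
        The iterative tau-a central-RDM optimization is only run when the
        RDMs have at most this many entries (it is quadratic in practice);
        above it, the mean of the rank-transformed RDMs is used directly
        and the upper bound is approximate.
    """
    if method not in COMPARISON_METHODS:
        raise ValueError(f"method must be one of {COMPARISON_METHODS}")
    k = len(subject_rdms)
    if k < 2:
        raise ValueError(f"noise ceiling needs >= 2 subject RDMs, got {k}")
    if k == 2:
        logger.warning(
            "noise ceiling with only 2 subjects: the lower bound degenerates "
            "to the correlation between the two subject RDMs"
        )
    transform = _CENTRAL_TRANSFORM[method]
    raw = subject_rdms.stack()
    transformed = np.stack(
        [
            transform_vector(v, transform, name=subject_rdms.names[i])
            for i, v in enumerate(raw)
        ]
    )

    central = transformed.mean(axis=0)
    if method == "kendall_tau_a" and central.size <= refine_max_pairs:
        central = _refine_tau_a_central(
            central, raw, tol=refine_tol, max_sweeps=refine_max_sweeps
        )
    elif method == "kendall_tau_a":
        logger.info(
            "tau-a central-RDM refinement skipped for %d pairs (> %d); "
            "upper bound uses the rank-mean initialization",
            central.size,
            refine_max_pairs,
        )

    upper = _mean_corr(central, raw, method)

    loo = []
    for i in range(k):
        others = np.delete(transformed, i, axis=0).mean(axis=0)
        loo.append(compare_vectors(others, raw[i], method))
    lower = float(np.mean(loo))

    return NoiseCeiling(lower=lower, upper=upper, method=method, n_subjects=k)
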