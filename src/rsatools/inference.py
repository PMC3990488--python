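"""Nonparametric statistical inference relating candidate RDMs to a reference.

Implements the default test-selection logic (signed-rank across subjects for
12 or more subjects; stimulus-label randomization plus stimulus bootstrap
otherwise, requiring at least 20 conditions), relatedness and
candidate-comparison tests, multiple-testing control (Benjamini-Hochberg FDR
by default, Bonferroni FWE as alternative), and the assembled
:class:`InferenceResult`.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.stats import rankdata, wilcoxon

from .ceiling import NoiseCeiling, estimate_noise_ceiling
from .compare import COMPARISON_METHODS, compare_vectors, kendall_tau_a
from .rdm import RDM, RDMCollection, n_pairs

__all__ = [
    "MIN_SUBJECTS_SIGNED_RANK",
    "MIN_CONDITIONS_RANDOMIZATION",
    "TestPlan",
    "InferenceResult",
    "RandomizationTestResult",
    "BootstrapResult",
    "select_tests",
    "test_relatedness_signed_rank",
    "test_relatedness_randomization",
    "compare_candidates_signed_rank",
    "compare_candidates_bootstrap",
    "adjust_multiple",
    "run_inference",
    "signed_rank_p",
]

logger = logging.getLogger(__name__)

#: Minimum subject count for across-subject signed-rank tests (default path).
MIN_SUBJECTS_SIGNED_RANK = 12

#: Minimum condition count accepted for stimulus-label randomization.
MIN_CONDITIONS_RANDOMIZATION = 20

RELATEDNESS_TESTS = ("signed_rank_across_subjects", "stimulus_label_randomization")
COMPARISON_TESTS = ("signed_rank_across_subjects", "bootstrap")
BOOTSTRAP_UNITS = ("stimuli", "subjects", "both", "none")


@dataclass
class TestPlan:
    """Selected inference procedures plus reproducibility parameters."""

    relatedness_test: str
    comparison_test: str
    bootstrap_unit: str = "none"
    n_permutations: int = 10_000
    n_bootstrap: int = 1_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.relatedness_test not in RELATEDNESS_TESTS:
            raise ValueError(f"unknown relatedness test {self.relatedness_test!r}")
        if self.comparison_test not in COMPARISON_TESTS:
            raise ValueError(f"unknown comparison test {self.comparison_test!r}")
        if self.bootstrap_unit not in BOOTSTRAP_UNITS:
            raise ValueError(f"unknown bootstrap unit {self.bootstrap_unit!r}")


def select_tests(
    n_subjects: int,
    n_conditions: int,
    overrides: Optional[dict] = None,
    min_subjects: int = MIN_SUBJECTS_SIGNED_RANK,
    min_conditions: int = MIN_CONDITIONS_RANDOMIZATION,
    **plan_kwargs,
) -> TestPlan:
    """Default decision process for choosing the statistical tests.

    With ``min_subjects`` (12) or more subjects, both the relatedness and
    the candidate-comparison test are signed-rank tests across subjects
    (random-effects, generalizing to the population).  With fewer subjects
    but at least ``min_conditions`` (20) conditions, relatedness is tested
    by stimulus-label randomization (fixed-effects) and comparisons by
    bootstrap resampling of the stimulus set.  Explicit ``overrides`` are
    honored with a logged notice, except that randomization below the
    condition minimum is always refused.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if n_conditions < 2:
        raise ValueError("need at least two conditions")

    if n_subjects >= min_subjects:
        plan = TestPlan(
            relatedness_test="signed_rank_across_subjects",
            comparison_test="signed_rank_across_subjects",
            bootstrap_unit="none",
            **plan_kwargs,
        )
    elif n_conditions >= min_conditions:
        plan = TestPlan(
            relatedness_test="stimulus_label_randomization",
            comparison_test="bootstrap",
            bootstrap_unit="stimuli",
            **plan_kwargs,
        )
    else:
        raise ValueError(
            f"no default test available: {n_subjects} subjects is below the "
            f"signed-rank minimum of {min_subjects}, and {n_conditions} "
            f"conditions is below the randomization minimum of "
            f"{min_conditions}; pass overrides to request a test explicitly"
        )

    if overrides:
        for key, value in overrides.items():
            if not hasattr(plan, key):
                raise ValueError(f"unknown TestPlan field {key!r}")
            if (
                key == "relatedness_test"
                and value == "stimulus_label_randomization"
                and n_conditions < min_conditions
            ):
                raise ValueError(
                    f"stimulus-label randomization requires >= {min_conditions} "
                    f"conditions, got {n_conditions}"
                )
            logger.info("test-selection override: %s = %r", key, value)
            setattr(plan, key, value)
        plan.__post_init__()
    return plan


# ---------------------------------------------------------------------------
# signed-rank machinery


def signed_rank_p(values: np.ndarray, alternative: str = "greater") -> float:
    """One-sample Wilcoxon signed-rank p-value against a zero median.

    Zero values are dropped before ranking (Wilcoxon convention); if all
    values are zero the test is uninformative and p = 1 is returned with a
    warning.  The exact null distribution is used for n <= 25 (tie-free
    absolute values), the normal approximation otherwise.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[v != 0]
    if v.size == 0:
        warnings.warn("all values are zero; signed-rank p set to 1", stacklevel=2)
        return 1.0
    tie_free = np.unique(np.abs(v)).size == v.size
    method = "exact" if (v.size <= 25 and tie_free) else "approx"
    return float(wilcoxon(v, alternative=alternative, method=method).pvalue)


def _per_subject_correlations(
    subject_rdms: RDMCollection, candidate: RDM, method: str
) -> np.ndarray:
    return np.array(
        [
            compare_vectors(candidate.dissimilarities, s, method)
            for s in subject_rdms.stack()
        ]
    )


def test_relatedness_signed_rank(
    subject_rdms: RDMCollection, candidate: RDM, method: str = "kendall_tau_a"
) -> float:
    """One-sided signed-rank test of candidate-reference relatedness.

    The statistic per subject is the correlation between the candidate RDM
    and that subject's reference-RDM estimate; the test asks whether these
    correlations are positive across subjects.
    """
    if candidate.condition_labels != subject_rdms.condition_labels:
        raise ValueError(
            f"candidate {candidate.name!r} does not share the subjects' condition set"
        )
    corrs = _per_subject_correlations(subject_rdms, candidate, method)
    return signed_rank_p(corrs, alternative="greater")


# ---------------------------------------------------------------------------
# stimulus-label randomization


def _pair_index_matrix(n_conditions: int) -> np.ndarray:
    """n x n matrix mapping condition pair (i, j) to its vector index."""
    idx = np.zeros((n_conditions, n_conditions), dtype=np.int64)
    iu = np.triu_indices(n_conditions, k=1)
    idx[iu] = np.arange(n_pairs(n_conditions))
    return idx + idx.T


def _permuted_vector_indices(perm: np.ndarray, idx: np.ndarray, iu) -> np.ndarray:
    return idx[np.ix_(perm, perm)][iu]


@dataclass(frozen=True)
class RandomizationTestResult:
    """Outcome of a stimulus-label randomization test."""

    p_value: float
    observed: float
    n_permutations: int
    exhaustive: bool
    method: str

    def __float__(self) -> float:
        return self.p_value


def test_relatedness_randomization(
    subject_rdms: RDMCollection,
    candidate: RDM,
    method: str = "spearman",
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    min_conditions: int = MIN_CONDITIONS_RANDOMIZATION,
    allow_small: bool = False,
) -> RandomizationTestResult:
    """Fixed-effects stimulus-label randomization test of RDM relatedness.

    The null distribution is built by re-ordering the condition labels (one
    permutation applied identically to rows and columns) and recomputing the
    statistic — the mean over subjects of the candidate-reference
    correlation.  When the number of distinct permutations
    ``n_conditions!`` does not exceed ``n_permutations``, all of them are
    enumerated and the p-value is the exact tail proportion; otherwise
    permutations are sampled and the (1 + k) / (1 + N) estimator is used so
    the p-value can never be 0.
    """
    if candidate.condition_labels != subject_rdms.condition_labels:
        raise ValueError("candidate does not share the subjects' condition set")
    n = subject_rdms.n_conditions
    if n < min_conditions and not allow_small:
        raise ValueError(
            f"stimulus-label randomization requires >= {min_conditions} "
            f"conditions, got {n}; pass allow_small=True to override"
        )
    if allow_small and n < min_conditions:
        logger.info(
            "randomization test explicitly requested with %d conditions "
            "(below the default minimum of %d)",
            n,
            min_conditions,
        )
    subjects = subject_rdms.stack()
    cand = candidate.dissimilarities
    idx = _pair_index_matrix(n)
    iu = np.triu_indices(n, k=1)

    exhaustive = math.factorial(n) <= n_permutations

    if method in ("pearson", "spearman"):
        # mean_i corr(x, y_i) = <standardize(x), mean_i standardize(y_i)> / m
        def standardize(v):
            r = rankdata(v) if method == "spearman" else v
            sd = r.std()
            if sd == 0:
                raise ValueError("constant vector: correlation undefined")
            return (r - r.mean()) / sd

        cand_z = standardize(cand)
        subj_mean_z = np.mean([standardize(s) for s in subjects], axis=0)
        m = cand.size

        def statistic_for(perm_idx):
            # entries of the candidate are merely reindexed, so its
            # standardized (rank) vector is reindexed the same way
            return float(cand_z[perm_idx] @ subj_mean_z) / m

    else:

        def statistic_for(perm_idx):
            pv = cand[perm_idx]
            return float(np.mean([kendall_tau_a(pv, s) for s in subjects]))

    identity = np.arange(n)
    observed = statistic_for(_permuted_vector_indices(identity, idx, iu))

    eps = 1e-12
    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = statistic_for(
                _permuted_vector_indices(np.array(perm), idx, iu)
            )
            total += 1
            if stat >= observed - eps:
                count += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            stat = statistic_for(_permuted_vector_indices(perm, idx, iu))
            if stat >= observed - eps:
                count += 1
        p = (1 + count) / (1 + n_permutations)
        n_used = n_permutations

    return RandomizationTestResult(
        p_value=float(p),
        observed=observed,
        n_permutations=n_used,
        exhaustive=exhaustive,
        method=method,
    )


# ---------------------------------------------------------------------------
# candidate comparison


def compare_candidates_signed_rank(
    subject_rdms: RDMCollection,
    candidates: RDMCollection,
    method: str = "kendall_tau_a",
    min_subjects: int = 4,
) -> np.ndarray:
    """Two-sided signed-rank tests on per-subject correlation differences.

    Returns the raw (unadjusted) M x M p-value matrix with NaN diagonal.
    """
    if candidates.condition_labels != subject_rdms.condition_labels:
        raise ValueError("candidates do not share the subjects' condition set")
    if len(subject_rdms) < min_subjects:
        raise ValueError(
            f"signed-rank comparison needs >= {min_subjects} subjects, "
            f"got {len(subject_rdms)}"
        )
    corrs = np.stack(
        [
            _per_subject_correlations(subject_rdms, c, method)
            for c in candidates
        ]
    )  # (M, n_subjects)
    m = len(candidates)
    p = np.full((m, m), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # identical candidates -> all-zero diffs
        for i in range(m):
            for j in range(i + 1, m):
                pij = signed_rank_p(corrs[i] - corrs[j], alternative="two-sided")
                p[i, j] = p[j, i] = pij
    return p


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap candidate-comparison outcome."""

    p_matrix: np.ndarray
    error_bars: np.ndarray
    statistics: np.ndarray  # (n_bootstrap, n_candidates)
    observed: np.ndarray
    unit: str
    n_redrawn: int


def compare_candidates_bootstrap(
    subject_rdms: RDMCollection,
    candidates: RDMCollection,
    unit: str = "stimuli",
    method: str = "spearman",
    n_bootstrap: int = 1_000,
    seed: Optional[int] = None,
) -> BootstrapResult:
    """Bootstrap test of pairwise candidate-performance differences.

    Stimuli and/or subjects are resampled with replacement.  After stimulus
    resampling, pairs formed by duplicate draws of the same condition are
    excluded from the correlations (their dissimilarity is structurally 0
    and would bias rank correlations).  The p-value for a candidate pair is
    the two-sided tail proportion of the bootstrap difference distribution
    around 0; the per-candidate error bar is the bootstrap standard
    deviation of its statistic.
    """
    if unit not in ("stimuli", "subjects", "both"):
        raise ValueError(f"bootstrap unit must be stimuli/subjects/both, got {unit!r}")
    if n_bootstrap < 100:
        raise ValueError(f"n_bootstrap must be >= 100, got {n_bootstrap}")
    n = subject_rdms.n_conditions
    if unit in ("stimuli", "both") and n < 5:
        raise ValueError(f"stimulus resampling requires >= 5 conditions, got {n}")
    if candidates.condition_labels != subject_rdms.condition_labels:
        raise ValueError("candidates do not share the subjects' condition set")

    subjects = subject_rdms.stack()
    cands = candidates.stack()
    k_subj = subjects.shape[0]
    m_cand = cands.shape[0]
    idx = _pair_index_matrix(n)
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)

    def statistic(subj_rows: np.ndarray, pair_idx: np.ndarray, valid: np.ndarray):
        out = np.empty(m_cand)
        sub = subj_rows[:, pair_idx][:, valid]
        for ci in range(m_cand):
            cv = cands[ci, pair_idx][valid]
            vals = []
            for s in sub:
                try:
                    vals.append(compare_vectors(cv, s, method))
                except ValueError:
                    vals.append(np.nan)
            out[ci] = np.nanmean(vals)
        return out

    identity_idx = idx[iu]
    observed = statistic(subjects, identity_idx, np.ones(identity_idx.size, bool))

    stats = np.empty((n_bootstrap, m_cand))
    n_redrawn = 0
    for b in range(n_bootstrap):
        while True:
            cond_sample = (
                rng.integers(0, n, size=n)
                if unit in ("stimuli", "both")
                else np.arange(n)
            )
            if np.unique(cond_sample).size >= 3:
                break
            n_redrawn += 1
        subj_sample = (
            rng.integers(0, k_subj, size=k_subj)
            if unit in ("subjects", "both")
            else np.arange(k_subj)
        )
        pair_idx = idx[np.ix_(cond_sample, cond_sample)][iu]
        valid = cond_sample[iu[0]] != cond_sample[iu[1]]
        stats[b] = statistic(subjects[subj_sample], pair_idx, valid)
    if n_redrawn:
        logger.info("redrew %d bootstrap samples with < 3 distinct conditions", n_redrawn)

    p = np.full((m_cand, m_cand), np.nan)
    for i in range(m_cand):
        for j in range(i + 1, m_cand):
            diffs = stats[:, i] - stats[:, j]
            tail = 2 * min(np.mean(diffs <= 0), np.mean(diffs >= 0))
            p[i, j] = p[j, i] = min(1.0, float(tail))
    error_bars = stats.std(axis=0, ddof=1)
    return BootstrapResult(
        p_matrix=p,
        error_bars=error_bars,
        statistics=stats,
        observed=observed,
        unit=unit,
        n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# multiple testing


def adjust_multiple(
    p_values: np.ndarray, procedure: str = "fdr_bh", alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Multiple-testing control: BH step-up FDR (default) or Bonferroni FWE.

    Returns the boolean rejection mask and the p-value threshold applied
    (0 when nothing is rejected under BH).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if procedure == "fwe_bonferroni":
        threshold = alpha / m
        return p <= threshold, threshold
    if procedure != "fdr_bh":
        raise ValueError(f"unknown procedure {procedure!r}")
    order = np.argsort(p)
    sorted_p = p[order]
    crit = alpha * np.arange(1, m + 1) / m
    below = np.flatnonzero(sorted_p <= crit)
    if below.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    threshold = sorted_p[below[-1]]
    return p <= threshold, float(threshold)


# ---------------------------------------------------------------------------
# assembled analysis


@dataclass
class InferenceResult:
    """Full candidate-versus-reference inference output."""

    candidate_names: tuple[str, ...]
    mean_corr: np.ndarray
    relatedness_p: np.ndarray
    pairwise_p: np.ndarray
    pairwise_reject: np.ndarray
    error_bars: np.ndarray
    ceiling: NoiseCeiling
    noise_flags: tuple[bool, ...]
    tests_used: dict

    def to_dict(self) -> dict:
        return {
            "candidate_names": list(self.candidate_names),
            "mean_corr": self.mean_corr.tolist(),
            "relatedness_p": self.relatedness_p.tolist(),
            "pairwise_p": self.pairwise_p.tolist(),
            "pairwise_reject": self.pairwise_reject.tolist(),
            "error_bars": self.error_bars.tolist(),
            "ceiling": {
                "lower": self.ceiling.lower,
                "upper": self.ceiling.upper,
                "method": self.ceiling.method,
                "n_subjects": self.ceiling.n_subjects,
            },
            "noise_flags": list(self.noise_flags),
            "tests_used": self.tests_used,
        }


def run_inference(
    subject_rdms: RDMCollection,
    candidates: RDMCollection,
    plan: Optional[TestPlan] = None,
    method: str = "kendall_tau_a",
    mc_procedure: str = "fdr_bh",
    alpha: float = 0.05,
    ceiling_kwargs: Optional[dict] = None,
) -> InferenceResult:
    """Relate every candidate RDM to the reference and compare candidates.

    Bar heights are the mean over subjects of the candidate-reference
    correlations; relatedness p-values and the adjusted pairwise-difference
    matrix follow the chosen :class:`TestPlan` (auto-selected when absent).
    Candidates tagged as subject estimates (noise-affected) are flagged:
    their performance comparisons with noiseless models should not be
    formally interpreted.
    """
    if plan is None:
        plan = select_tests(len(subject_rdms), subject_rdms.n_conditions)
    names = candidates.names
    m = len(candidates)

    corrs = np.stack(
        [_per_subject_correlations(subject_rdms, c, method) for c in candidates]
    )
    mean_corr = corrs.mean(axis=1)

    if plan.relatedness_test == "signed_rank_across_subjects":
        relatedness = np.array(
            [signed_rank_p(row, alternative="greater") for row in corrs]
        )
    else:
        relatedness = np.array(
            [
                test_relatedness_randomization(
                    subject_rdms,
                    c,
                    method=method,
                    n_permutations=plan.n_permutations,
                    seed=None if plan.seed is None else plan.seed + ci,
                ).p_value
                for ci, c in enumerate(candidates)
            ]
        )

    if plan.comparison_test == "signed_rank_across_subjects":
        raw_pairwise = compare_candidates_signed_rank(subject_rdms, candidates, method)
        error_bars = corrs.std(axis=1, ddof=1) / np.sqrt(corrs.shape[1])
    else:
        boot = compare_candidates_bootstrap(
            subject_rdms,
            candidates,
            unit=plan.bootstrap_unit if plan.bootstrap_unit != "none" else "stimuli",
            method=method,
            n_bootstrap=plan.n_bootstrap,
            seed=plan.seed,
        )
        raw_pairwise = boot.p_matrix
        error_bars = boot.error_bars

    iu = np.triu_indices(m, k=1)
    reject_flat, threshold = adjust_multiple(
        raw_pairwise[iu], procedure=mc_procedure, alpha=alpha
    ) if m > 1 else (np.zeros(0, bool), 0.0)
    pairwise_reject = np.zeros((m, m), dtype=bool)
    pairwise_reject[iu] = reject_flat
    pairwise_reject |= pairwise_reject.T

    ceiling = estimate_noise_ceiling(
        subject_rdms, method=method, **(ceiling_kwargs or {})
    )

    noise_flags = tuple(role == "subject_estimate" for role in candidates.roles)
    tests_used = {
        "plan": asdict(plan),
        "method": method,
        "mc_procedure": mc_procedure,
        "alpha": alpha,
        "mc_threshold": threshold,
        "n_subjects": len(subject_rdms),
        "n_conditions": subject_rdms.n_conditions,
    }
    return InferenceResult(
        candidate_names=names,
        mean_corr=mean_corr,
        relatedness_p=relatedness,
        pairwise_p=raw_pairwise,
        pairwise_reject=pairwise_reject,
        error_bars=error_bars,
        ceiling=ceiling,
        noise_flags=noise_flags,
        tests_used=tests_used,
    )
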