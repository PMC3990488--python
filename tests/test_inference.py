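import itertools
import logging

import numpy as np
import pytest
from scipy.stats import kstest

from rsatools.inference import (
    adjust_multiple,
    compare_candidates_bootstrap,
    compare_candidates_signed_rank,
    run_inference,
    select_tests,
    signed_rank_p,
)
from rsatools.inference import test_relatedness_randomization as relatedness_randomization
from rsatools.inference import test_relatedness_signed_rank as relatedness_signed_rank
from rsatools.rdm import RDM, RDMCollection, n_pairs
from .conftest import labels, random_collection, random_rdm


class TestSelectTests:
    def test_many_subjects_default_signed_rank(self):
        plan = select_tests(12, 92)
        assert plan.relatedness_test == "signed_rank_across_subjects"
        assert plan.comparison_test == "signed_rank_across_subjects"

    def test_few_subjects_many_conditions(self):
        plan = select_tests(4, 92)
        assert plan.relatedness_test == "stimulus_label_randomization"
        assert plan.comparison_test == "bootstrap"
        assert plan.bootstrap_unit == "stimuli"

    def test_few_conditions_forces_signed_rank(self):
        plan = select_tests(20, 6)
        assert plan.relatedness_test == "signed_rank_across_subjects"

    def test_neither_criterion_met_errors_explaining_both(self):
        with pytest.raises(ValueError) as err:
            select_tests(4, 6)
        assert "12" in str(err.value) and "20" in str(err.value)

    def test_override_honored_with_notice(self, caplog):
        with caplog.at_level(logging.INFO, logger="rsatools.inference"):
            plan = select_tests(
                20, 92, overrides={"relatedness_test": "stimulus_label_randomization"}
            )
        assert plan.relatedness_test == "stimulus_label_randomization"
        assert "override" in caplog.text

    def test_randomization_override_refused_below_condition_minimum(self):
        with pytest.raises(ValueError, match=">= 20"):
            select_tests(
                20, 6, overrides={"relatedness_test": "stimulus_label_randomization"}
            )


class TestSignedRank:
    def test_smallest_exact_p_at_n12(self):
        assert signed_rank_p(np.arange(1, 13.0)) == pytest.approx(2**-12)

    def test_symmetric_alternating_values_not_significant(self):
        v = np.array([1.0, -1.0] * 6) * np.repeat(np.arange(1, 7), 2)[::2].repeat(2)[:12]
        v = np.array([c * (1 if i % 2 == 0 else -1) for i, c in enumerate([1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6.0])])
        assert signed_rank_p(v) >= 0.5

    def test_all_zero_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            assert signed_rank_p(np.zeros(5)) == 1.0

    def test_exact_null_matches_full_enumeration(self, rng):
        # n <= 12: compare against full 2^n sign enumeration
        n = 9
        v = rng.standard_normal(n)
        v = np.where(np.abs(v) < 1e-3, 0.5, v)  # keep away from zero
        # tie-free magnitudes with probability 1
        ranks = np.argsort(np.argsort(np.abs(v))) + 1
        w_obs = ranks[v > 0].sum()
        count = sum(
            1
            for signs in itertools.product([0, 1], repeat=n)
            if ranks[np.array(signs, dtype=bool)].sum() >= w_obs
        )
        assert signed_rank_p(v, "greater") == pytest.approx(count / 2**n)

    def test_relatedness_positive_candidate(self, rng):
        base = random_rdm(rng, 8, name="truth")
        noisy = tuple(
            base.with_dissimilarities(
                base.dissimilarities + 0.1 * rng.standard_normal(base.n_pairs),
                name=f"s{i}",
            )
            for i in range(12)
        )
        coll = RDMCollection(rdms=noisy)
        # all 12 per-subject correlations positive; exact p is 2^-12 unless
        # coincidentally tied correlation values force the approximation
        assert relatedness_signed_rank(coll, base, "spearman") < 0.002

    @pytest.mark.slow
    def test_null_calibration(self, rng):
        # candidate independent of the data: type-I error near nominal
        n_rep, alpha = 1000, 0.05
        hits = 0
        for _ in range(n_rep):
            coll = random_collection(rng, n_rdms=12, n_conditions=6)
            cand = random_rdm(rng, 6)
            p = relatedness_signed_rank(coll, cand, "spearman")
            hits += p <= alpha
        assert 0.03 <= hits / n_rep <= 0.07


class TestRandomization:
    def test_exhaustive_identity_only_max(self, rng):
        vec = rng.random(n_pairs(5))
        rdm = RDM(labels(5), vec, name="ref")
        coll = RDMCollection(rdms=(rdm,))
        res = relatedness_randomization(
            coll, rdm, method="spearman", n_permutations=10_000, allow_small=True
        )
        assert res.exhaustive
        assert res.n_permutations == 120
        assert res.p_value == pytest.approx(1 / 120)

    def test_six_conditions_enumerates_720(self, rng):
        rdm = random_rdm(rng, 6)
        coll = RDMCollection(rdms=(rdm,))
        res = relatedness_randomization(
            coll, rdm, method="spearman", n_permutations=10_000, allow_small=True
        )
        assert res.exhaustive and res.n_permutations == 720

    def test_condition_minimum_enforced(self, rng):
        rdm = random_rdm(rng, 6)
        coll = RDMCollection(rdms=(rdm,))
        with pytest.raises(ValueError, match=">= 20 conditions"):
            relatedness_randomization(coll, rdm)

    def test_p_never_zero_nor_above_one(self, rng):
        coll = random_collection(rng, n_rdms=2, n_conditions=20)
        cand = random_rdm(rng, 20)
        res = relatedness_randomization(
            coll, cand, n_permutations=200, seed=0
        )
        assert 0 < res.p_value <= 1

    def test_tau_a_path_agrees_with_generic_statistic(self, rng):
        coll = random_collection(rng, n_rdms=2, n_conditions=6)
        cand = random_rdm(rng, 6)
        res = relatedness_randomization(
            coll, cand, method="kendall_tau_a", n_permutations=720, allow_small=True
        )
        assert res.exhaustive
        assert 0 < res.p_value <= 1

    @pytest.mark.slow
    def test_null_p_uniform(self, rng):
        pvals = []
        for _ in range(500):
            coll = random_collection(rng, n_rdms=2, n_conditions=20)
            cand = random_rdm(rng, 20)
            pvals.append(
                relatedness_randomization(
                    coll, cand, n_permutations=199, seed=int(rng.integers(2**31))
                ).p_value
            )
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCompareCandidates:
    def test_duplicate_candidate_p_one(self, rng):
        coll = random_collection(rng, n_rdms=12, n_conditions=6)
        cand = random_rdm(rng, 6, name="m")
        cands = RDMCollection(rdms=(cand, cand), roles=("candidate", "candidate"))
        p = compare_candidates_signed_rank(coll, cands, "spearman")
        assert p[0, 1] == pytest.approx(1.0)
        assert np.isnan(p[0, 0])

    def test_symmetry(self, rng):
        coll = random_collection(rng, n_rdms=12, n_conditions=6)
        cands = random_collection(
            rng, n_rdms=3, n_conditions=6, roles=("candidate",) * 3
        )
        p = compare_candidates_signed_rank(coll, cands, "spearman")
        np.testing.assert_array_equal(p[np.triu_indices(3, 1)], p.T[np.triu_indices(3, 1)])

    def test_bootstrap_identical_candidates_p_one(self, rng):
        coll = random_collection(rng, n_rdms=3, n_conditions=10)
        cand = random_rdm(rng, 10, name="m")
        cands = RDMCollection(rdms=(cand, cand), roles=("candidate",) * 2)
        res = compare_candidates_bootstrap(
            coll, cands, unit="stimuli", n_bootstrap=100, seed=0
        )
        assert res.p_matrix[0, 1] == pytest.approx(1.0)

    def test_bootstrap_error_bars_positive(self, rng):
        coll = random_collection(rng, n_rdms=3, n_conditions=10)
        cands = random_collection(
            rng, n_rdms=2, n_conditions=10, roles=("candidate",) * 2
        )
        res = compare_candidates_bootstrap(
            coll, cands, unit="stimuli", n_bootstrap=100, seed=0
        )
        assert np.all(res.error_bars > 0)

    @pytest.mark.slow
    def test_bootstrap_sd_shrinks_with_condition_count(self):
        # bootstrap SD of the mean correlation ~ 1/sqrt(n_conditions); the
        # candidate is the noiseless RDM of directly generated patterns so
        # the signal level is matched across condition counts
        from rsatools.rdm import PatternSet, compute_rdm
        from rsatools.simulate import SimulationSpec, noisy_subjects

        sds = {}
        for n_cond in (40, 160):
            rng = np.random.default_rng(5)
            truth = PatternSet(
                labels(n_cond), rng.standard_normal((n_cond, 30)), name="truth"
            )
            base = compute_rdm(truth, "euclidean", name="gt")
            subs = noisy_subjects(
                truth,
                SimulationSpec(n_channels=30, noise_sd=0.5, n_subjects=2, seed=2),
            )
            coll = RDMCollection(
                rdms=tuple(compute_rdm(p, "euclidean", name=p.name) for p in subs)
            )
            cands = RDMCollection(rdms=(base,), roles=("candidate",))
            res = compare_candidates_bootstrap(
                coll, cands, unit="stimuli", n_bootstrap=150, seed=3
            )
            sds[n_cond] = res.error_bars[0]
        ratio = sds[40] / sds[160]
        assert 2.0 / 1.5 <= ratio <= 2.0 * 1.5


class TestAdjustMultiple:
    def test_bh_step_up_hand_case(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.5])
        mask, threshold = adjust_multiple(p, "fdr_bh", 0.05)
        np.testing.assert_array_equal(mask, [True, True, True, True, False])
        assert threshold == pytest.approx(0.04)

    def test_all_small_rejected_by_both(self):
        p = np.full(10, 0.001)
        for proc in ("fdr_bh", "fwe_bonferroni"):
            mask, _ = adjust_multiple(p, proc, 0.05)
            assert mask.all()

    def test_bh_dominates_bonferroni(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 20))
            bh, _ = adjust_multiple(p, "fdr_bh", 0.05)
            bonf, _ = adjust_multiple(p, "fwe_bonferroni", 0.05)
            assert np.all(bh | ~bonf)  # bonferroni rejections subset of BH

    def test_empty_input(self):
        mask, threshold = adjust_multiple(np.array([]), "fdr_bh", 0.05)
        assert mask.size == 0

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(20)
            mask, _ = adjust_multiple(p, "fdr_bh", 0.05)
            oracle = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(mask, oracle)


class TestRunInference:
    def _setup(self, rng, n_subjects=12, n_conditions=8, n_candidates=3):
        base = random_rdm(rng, n_conditions, name="truth")
        subs = tuple(
            base.with_dissimilarities(
                base.dissimilarities + 0.3 * rng.standard_normal(base.n_pairs),
                name=f"s{i}",
            )
            for i in range(n_subjects)
        )
        coll = RDMCollection(rdms=subs)
        cands = RDMCollection(
            rdms=(base,)
            + tuple(random_rdm(rng, n_conditions, name=f"m{i}") for i in range(n_candidates - 1)),
            roles=("candidate",) * n_candidates,
        )
        return coll, cands

    def test_single_candidate_empty_pairwise(self, rng):
        coll, cands = self._setup(rng, n_candidates=1)
        result = run_inference(coll, cands, method="spearman")
        assert result.relatedness_p.size == 1
        assert result.pairwise_p.shape == (1, 1)
        assert not result.pairwise_reject.any()

    def test_deterministic_given_seed(self, rng):
        coll, cands = self._setup(rng, n_subjects=4, n_conditions=20)
        plan = select_tests(4, 20, seed=7, n_permutations=100, n_bootstrap=100)
        r1 = run_inference(coll, cands, plan=plan, method="spearman")
        r2 = run_inference(coll, cands, plan=plan, method="spearman")
        np.testing.assert_array_equal(r1.relatedness_p, r2.relatedness_p)
        np.testing.assert_array_equal(r1.pairwise_p, r2.pairwise_p)
        np.testing.assert_array_equal(r1.error_bars, r2.error_bars)

    def test_noise_flagged_candidates(self, rng):
        coll, _ = self._setup(rng)
        cands = RDMCollection(
            rdms=(random_rdm(rng, 8, name="model"), random_rdm(rng, 8, name="brain")),
            roles=("candidate", "subject_estimate"),
        )
        result = run_inference(coll, cands, method="spearman")
        assert result.noise_flags == (False, True)

    def test_true_candidate_ranks_first_and_related(self, rng):
        coll, cands = self._setup(rng)
        result = run_inference(coll, cands, method="spearman")
        assert np.argmax(result.mean_corr) == 0
        assert result.relatedness_p[0] < 0.01
        assert result.ceiling.lower <= result.ceiling.upper + 1e-9
        assert result.tests_used["plan"]["relatedness_test"] == (
            "signed_rank_across_subjects"
        )


@pytest.mark.slow
def test_true_vs_worst_candidate_power():
    # scaled-down simulated group scenario: the true model beats the
    # unrelated control significantly in nearly all replicates
    from rsatools.simulate import make_fig4_scenario

    wins = 0
    n_rep = 10
    for seed in range(n_rep):
        sc = make_fig4_scenario(seed=seed, n_conditions=24, n_channels=40)
        p = compare_candidates_signed_rank(
            sc.subject_rdms, sc.candidates, "spearman"
        )
        worst = len(sc.candidates) - 1  # unrelated control
        wins += p[0, worst] < 0.05
    assert wins >= 0.9 * n_rep


@pytest.mark.slow
def test_bh_controls_empirical_fdr(rng):
    # all-null simulation at m=50: empirical FDR (= FWER here) <= alpha + tol
    m, n_rep, alpha = 50, 2000, 0.05
    fdp = []
    for _ in range(n_rep):
        p = rng.random(m)
        mask, _ = adjust_multiple(p, "fdr_bh", alpha)
        n_rej = mask.sum()
        fdp.append(0.0 if n_rej == 0 else 1.0)  # all rejections are false
    assert np.mean(fdp) <= alpha + 0.02
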