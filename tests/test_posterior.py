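import math

import numpy as np
import pytest

from asc import (
    CountTable,
    GeneResult,
    Hyperparameters,
    PosteriorGridConfig,
    bayesian_fdr,
    compute_posterior,
    log_unnormalized_posterior,
    prob_exceeds,
    run_asc,
)

M = 10**6
LOG10_2 = math.log10(2.0)


class TestLogUnnormalizedPosterior:
    def test_swap_symmetry_at_equal_depths(self, hyper):
        d = np.linspace(-1, 1, 11)
        lam = -4.0
        a = log_unnormalized_posterior(20, 5, M, M, d, lam, hyper)
        b = log_unnormalized_posterior(5, 20, M, M, -d, lam, hyper)
        np.testing.assert_array_equal(a, b)

    def test_impossible_proportion_marked(self, hyper):
        # lambda + delta/2 = 0.5 would mean a proportion above 1
        val = log_unnormalized_posterior(3, 3, M, M, 1.2, -0.1, hyper)
        assert val == -np.inf

    def test_double_zero_counts_still_finite(self, hyper):
        val = log_unnormalized_posterior(0, 0, M, M, 0.3, -5.0, hyper)
        assert np.isfinite(val)

    def test_poisson_close_to_binomial_at_small_proportion(self, hyper):
        d, lam = 0.2, -4.5
        b = log_unnormalized_posterior(30, 20, M, M, d, lam, hyper, "binomial")
        p = log_unnormalized_posterior(30, 20, M, M, d, lam, hyper, "poisson")
        # normalizations differ by a per-gene constant; compare differences
        b2 = log_unnormalized_posterior(30, 20, M, M, 0.0, lam, hyper, "binomial")
        p2 = log_unnormalized_posterior(30, 20, M, M, 0.0, lam, hyper, "poisson")
        assert (b - b2) == pytest.approx(p - p2, abs=1e-4)


class TestComputePosterior:
    def test_symmetric_counts_give_zero_mean(self, hyper):
        s = compute_posterior(100, 100, M, M, hyper)
        assert abs(s.delta_hat) < 1e-9

    def test_antisymmetric_under_sample_swap(self, hyper):
        a = compute_posterior(20, 5, M, M, hyper)
        b = compute_posterior(5, 20, M, M, hyper)
        assert a.delta_hat == pytest.approx(-b.delta_hat, abs=1e-12)

    def test_marginal_is_a_proper_density(self, hyper):
        for x1, x2 in [(20, 5), (0, 3), (1000, 100), (50000, 50000)]:
            s = compute_posterior(x1, x2, M, M, hyper)
            assert float(s.weights @ s.density) == pytest.approx(1.0, abs=1e-9)
            assert np.all(s.density >= 0)

    def test_shrinkage_keeps_estimate_inside_apparent_ratio(self, hyper):
        s = compute_posterior(20, 5, M, M, hyper)
        assert 0.0 < s.delta_hat < math.log10(20 / 5)

    def test_stable_under_grid_halving(self, hyper):
        fine = PosteriorGridConfig(lambda_step=0.005, delta_step=0.0025)
        for x1, x2 in [(20, 5), (1, 0), (3000, 1000)]:
            a = compute_posterior(x1, x2, M, M, hyper)
            b = compute_posterior(x1, x2, M, M, hyper, fine)
            assert abs(a.delta_hat - b.delta_hat) < 1e-3

    def test_monotone_in_first_count(self, hyper):
        values = [compute_posterior(x1, 10, M, M, hyper).delta_hat
                  for x1 in (1, 5, 10, 30, 100, 400)]
        assert np.all(np.diff(values) > 0)

    def test_double_zero_rejected(self, hyper):
        with pytest.raises(ValueError, match="x1 \\+ x2"):
            compute_posterior(0, 0, M, M, hyper)

    def test_boundary_expansion_then_error(self):
        # wide posterior vs deliberately narrow fixed grid: first a one-time
        # expansion, then a hard error when mass still reaches the boundary
        wide = Hyperparameters(alpha=2.0, tau=0.5)
        ok = compute_posterior(
            1, 0, M, M, wide,
            PosteriorGridConfig(refine=False, delta_tau_mult=2.5, delta_se_mult=0.1),
        )
        assert ok.expanded
        with pytest.raises(RuntimeError, match="boundary"):
            compute_posterior(
                1, 0, M, M, wide,
                PosteriorGridConfig(refine=False, delta_tau_mult=0.8, delta_se_mult=0.1),
            )


class TestProbExceeds:
    def test_zero_threshold_is_certain(self, hyper):
        s = compute_posterior(20, 5, M, M, hyper)
        assert prob_exceeds(s, 0.0) == 1.0

    def test_beyond_grid_is_zero(self, hyper):
        s = compute_posterior(20, 5, M, M, hyper)
        assert prob_exceeds(s, 50.0) == 0.0

    def test_monotone_nonincreasing_in_threshold(self, hyper):
        s = compute_posterior(20, 5, M, M, hyper)
        probs = [prob_exceeds(s, d0) for d0 in np.linspace(0, 1.5, 40)]
        assert np.all(np.diff(probs) <= 1e-12)
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_negative_threshold_rejected(self, hyper):
        s = compute_posterior(20, 5, M, M, hyper)
        with pytest.raises(ValueError):
            prob_exceeds(s, -0.1)


class TestRunAsc:
    def test_identical_rows_identical_results_and_order(self, hyper):
        t = CountTable(
            np.array(["a", "b", "c"], dtype=object),
            np.array([20, 20, 5]),
            np.array([5, 5, 20]),
            M,
            M,
        )
        res = run_asc(t, hyper)
        assert [r.gene_id for r in res] == ["a", "b", "c"]
        assert res[0].delta_hat == res[1].delta_hat
        assert res[0].post_prob == res[1].post_prob

    def test_all_zero_table_flagged(self, hyper):
        t = CountTable(
            np.array(["a", "b"], dtype=object),
            np.array([0, 0]),
            np.array([0, 0]),
            M,
            M,
        )
        res = run_asc(t, hyper)
        assert all(r.flag == "no-signal" for r in res)
        assert all(r.delta_hat == 0.0 and r.post_prob == 0.0 for r in res)

    def test_deterministic(self, hyper, small_table):
        a = run_asc(small_table, hyper)
        b = run_asc(small_table, hyper)
        assert [(r.delta_hat, r.post_prob) for r in a] == [
            (r.delta_hat, r.post_prob) for r in b
        ]


class TestBayesianFdr:
    def test_mean_nonexceedance_over_selected(self):
        res = [
            GeneResult("a", 0.5, 0.95, 0.6, 1.0),
            GeneResult("b", 0.4, 0.91, 0.5, 1.0),
            GeneResult("c", 0.1, 0.30, 0.2, 1.0),
        ]
        selected, fdr = bayesian_fdr(res, 0.9)
        assert [r.gene_id for r in selected] == ["a", "b"]
        assert fdr == pytest.approx(0.07)

    def test_certain_calls_give_zero_fdr(self):
        res = [GeneResult(str(i), 1.0, 1.0, 1.0, 1.0) for i in range(3)]
        _, fdr = bayesian_fdr(res, 0.9)
        assert fdr == 0.0

    def test_empty_selection_marker(self):
        res = [GeneResult("a", 0.0, 0.1, 0.0, 1.0)]
        selected, fdr = bayesian_fdr(res, 0.9)
        assert selected == []
        assert math.isnan(fdr)

    def test_fdr_nonincreasing_in_cutoff(self):
        rng = np.random.default_rng(0)
        res = [GeneResult(str(i), 0.0, p, 0.0, 1.0) for i, p in
               enumerate(rng.uniform(size=200))]
        fdrs = [bayesian_fdr(res, c)[1] for c in (0.5, 0.7, 0.9)]
        assert fdrs[0] >= fdrs[1] >= fdrs[2]
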