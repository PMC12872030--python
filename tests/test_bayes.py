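"""Fractional Bayes factors, fit/complexity, PMPs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crtbayes import (
    FractionSpec,
    HypothesisSpec,
    bf_pair,
    bf_vs_complement,
    bf_vs_unconstrained,
    evaluate_hypotheses,
    fit_and_complexity,
    posterior_model_probabilities,
    prior_and_posterior,
)
from crtbayes.bayes import H1, Normal
from crtbayes.exceptions import UndefinedPmpError

# the motivating worked example: estimate 1.934, SE 0.555, N_eff 180.58
EX = dict(estimate=1.934, std_error=0.555, n1=12, n2=22, icc=0.042)


class TestPriorAndPosterior:
    def test_worked_example_prior_sd(self):
        frac = FractionSpec(n_eff=180.58, j_multiplier=1)
        prior, post = prior_and_posterior(None, frac, estimate=1.934,
                                          std_error=0.555)
        assert post == Normal(1.934, 0.555)
        assert prior.mean == 0.0
        assert prior.sd == pytest.approx(0.555 * math.sqrt(180.58), abs=5e-4)
        assert prior.sd == pytest.approx(7.458, abs=5e-3)

    def test_full_fraction_matches_posterior_sd(self):
        frac = FractionSpec(n_eff=1.0, j_multiplier=1)  # b = 1
        prior, post = prior_and_posterior(None, frac, estimate=0.3,
                                          std_error=0.2)
        assert prior.sd == pytest.approx(post.sd)

    def test_prior_variance_scaling_in_n_eff(self):
        p1, _ = prior_and_posterior(None, FractionSpec(100.0), estimate=0,
                                    std_error=1.0)
        p2, _ = prior_and_posterior(None, FractionSpec(200.0), estimate=0,
                                    std_error=1.0)
        assert p2.sd ** 2 == pytest.approx(2 * p1.sd ** 2)


class TestFitAndComplexity:
    def test_boundary_estimate_gives_half_fit(self):
        prior = Normal(0.0, 2.0)
        post = Normal(0.0, 0.5)
        f, c = fit_and_complexity(H1, prior, post)
        assert f == pytest.approx(0.5)
        assert c == pytest.approx(0.5)
        assert bf_vs_unconstrained(f, c) == pytest.approx(1.0)

    def test_saturation_at_two(self):
        f, c = fit_and_complexity(H1, Normal(0, 5.0), Normal(30.0, 1.0))
        assert f == pytest.approx(1.0, abs=1e-12)
        assert bf_vs_unconstrained(f, c) == pytest.approx(2.0, abs=1e-10)

    def test_monte_carlo_integration_oracle(self):
        """Analytic fit/complexity agree with 1e7-draw MC integration."""
        rng = np.random.default_rng(2024)
        n = 10_000_000
        prior = Normal(0.0, 7.458)
        post = Normal(1.934, 0.555)
        prior_draws = rng.normal(*prior, n)
        post_draws = rng.normal(*post, n)

        h1 = HypothesisSpec("greater")
        f1, c1 = fit_and_complexity(h1, prior, post)
        assert f1 == pytest.approx(np.mean(post_draws > 0), abs=2e-4)
        assert c1 == pytest.approx(np.mean(prior_draws > 0), abs=2e-4)

        h2 = HypothesisSpec("less_equal")
        f2, c2 = fit_and_complexity(h2, prior, post)
        assert f2 == pytest.approx(np.mean(post_draws <= 0), abs=2e-4)
        assert c2 == pytest.approx(np.mean(prior_draws <= 0), abs=2e-4)

        # equality: density at 0 via a narrow window around the boundary
        h0 = HypothesisSpec("equality")
        f0, c0 = fit_and_complexity(h0, prior, post)
        eps_p, eps_q = 0.02 * post.sd, 0.02 * prior.sd
        assert f0 == pytest.approx(
            np.mean(np.abs(post_draws) < eps_p) / (2 * eps_p), abs=2e-4)
        assert c0 == pytest.approx(
            np.mean(np.abs(prior_draws) < eps_q) / (2 * eps_q), abs=2e-4)

    def test_complement_of_equality_is_unconstrained(self):
        h = HypothesisSpec("complement",
                           complement_of=HypothesisSpec("equality"))
        assert fit_and_complexity(h, Normal(0, 2), Normal(1, 1)) == (1.0, 1.0)

    def test_complement_of_complement_rejected(self):
        hc = HypothesisSpec("complement", complement_of=H1)
        with pytest.raises(ValueError):
            HypothesisSpec("complement", complement_of=hc)


class TestBayesFactors:
    def test_worked_example_table(self):
        res = evaluate_hypotheses(**EX)
        t = res.table
        assert t.loc["H0", "fit"] == pytest.approx(0.002, abs=5e-4)
        assert t.loc["H0", "complexity"] == pytest.approx(0.053, abs=5e-4)
        assert t.loc["H0", "bf_u"] == pytest.approx(0.031, abs=5e-4)
        assert t.loc["H1", "fit"] == pytest.approx(1.0, abs=5e-4)
        assert t.loc["H1", "complexity"] == pytest.approx(0.5)
        assert t.loc["H1", "bf_u"] == pytest.approx(2.0, abs=1e-3)
        assert t.loc["H1", "bf_c"] > 1000
        assert t.loc["Hc", "bf_u"] == pytest.approx(0.0, abs=5e-4)
        # PMPs as printed: a = {H0,H1}; b adds Hu; c adds Hc
        assert t.loc["H1", "pmp_a"] == pytest.approx(0.985, abs=1e-3)
        assert t.loc["H0", "pmp_a"] == pytest.approx(0.015, abs=1e-3)
        assert t.loc["H1", "pmp_b"] == pytest.approx(0.66, abs=5e-3)
        assert t.loc["Hu", "pmp_b"] == pytest.approx(0.33, abs=5e-3)
        assert t.loc["H0", "pmp_b"] == pytest.approx(0.01, abs=5e-3)
        assert t.loc["H1", "pmp_c"] == pytest.approx(0.985, abs=1e-3)

    def test_bf_pair_printed_entries(self):
        # ratio of the printed BF_u entries
        assert bf_pair(2.0, 0.031) == pytest.approx(64.52, abs=0.005)

    def test_bf_vs_complement_hand_arithmetic(self):
        assert bf_vs_complement(0.8, 0.5) == pytest.approx(4.0)

    def test_bf_c_infinite_at_unit_fit(self):
        assert bf_vs_complement(1.0, 0.5) == math.inf

    def test_equality_bf_closed_form_at_null_estimate(self):
        # with estimate 0, BF_0u = sqrt(N_eff / J) exactly
        for j, n_eff in ((1, 180.58), (2, 180.58), (3, 64.0)):
            frac = FractionSpec(n_eff=n_eff, j_multiplier=j)
            prior, post = prior_and_posterior(None, frac, estimate=0.0,
                                              std_error=0.5)
            f, c = fit_and_complexity(HypothesisSpec("equality"), prior, post)
            assert f / c == pytest.approx(math.sqrt(n_eff / j), rel=1e-12)

    def test_bf1u_unit_at_null_estimate(self):
        res = evaluate_hypotheses(0.0, 0.5, 12, 22, 0.042)
        assert res["H1"]["bf_u"] == pytest.approx(1.0)

    def test_bf1u_monotone_in_estimate(self):
        values = [evaluate_hypotheses(e, 0.5, 12, 22, 0.042)["H1"]["bf_u"]
                  for e in (-1.0, -0.2, 0.0, 0.3, 1.0, 2.5)]
        assert all(a < b for a, b in zip(values, values[1:]))

    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.01, 100))
    def test_bf_pair_transitivity(self, bi, bj, bk):
        assert bf_pair(bi, bk) == pytest.approx(
            bf_pair(bi, bj) * bf_pair(bj, bk), rel=1e-9)


class TestPosteriorModelProbabilities:
    def test_printed_variant_b(self):
        pmp = posterior_model_probabilities({"H0": 0.031, "H1": 2.0, "Hu": 1.0})
        assert pmp["H1"] == pytest.approx(0.66, abs=5e-3)
        assert pmp["Hu"] == pytest.approx(0.33, abs=5e-3)
        assert pmp["H0"] == pytest.approx(0.01, abs=5e-3)

    def test_equal_bfs_give_equal_pmps(self):
        pmp = posterior_model_probabilities({"H0": 1.3, "H1": 1.3})
        assert pmp == {"H0": 0.5, "H1": 0.5}

    def test_variant_c_with_zero_complement(self):
        pmp = posterior_model_probabilities({"H0": 0.031, "H1": 2.0, "Hc": 0.0})
        assert pmp["H1"] == pytest.approx(0.985, abs=1e-3)
        assert pmp["H0"] == pytest.approx(0.015, abs=1e-3)
        assert pmp["Hc"] == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedPmpError):
            posterior_model_probabilities({"H0": 0.0, "H1": 0.0})

    @given(st.dictionaries(st.sampled_from(["H0", "H1", "Hu", "Hc"]),
                           st.floats(0.0, 50.0), min_size=2),)
    def test_normalization(self, bfs):
        if sum(bfs.values()) == 0:
            return
        pmp = posterior_model_probabilities(bfs)
        assert sum(pmp.values()) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-3, 3), st.floats(0.2, 2.0), st.integers(1, 3))
    def test_pmp_columns_sum_to_one(self, est, se, j):
        res = evaluate_hypotheses(est, se, 12, 22, 0.042, j_multiplier=j)
        t = res.table
        assert t["pmp_a"].sum() == pytest.approx(1.0)
        assert t["pmp_b"].sum() == pytest.approx(1.0)
        assert t["pmp_c"].sum() == pytest.approx(1.0)
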