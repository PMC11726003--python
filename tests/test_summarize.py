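"""Posterior summaries: R-hat, intervals, contrasts, effects, fit stats."""

import numpy as np
import pytest

from dendrosam import (
    bayesian_r2_rmse,
    effect_sizes,
    gelman_rubin,
    pairwise_treatment_differences,
    summarize_posterior,
)
from dendrosam.summarize import _split_rhat
from conftest import make_flat_design, make_posterior


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        rng = np.random.default_rng(0)
        one = rng.normal(size=1000)
        chains = np.stack([one, one, one])
        assert _split_rhat(chains) == pytest.approx(1.0, abs=1e-2)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert _split_rhat(chains) > 3.0

    def test_well_mixed_chains_near_one_and_match_arviz(self):
        import arviz as az

        rng = np.random.default_rng(2)
        chains = rng.normal(size=(3, 2000))
        ours = _split_rhat(chains)
        theirs = float(np.asarray(az.rhat(chains)))
        assert ours == pytest.approx(1.0, abs=0.01)
        assert ours == pytest.approx(theirs, abs=0.02)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin({"x": np.random.default_rng(0).normal(size=(1, 100))})

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="10 draws"):
            gelman_rubin({"x": np.zeros((2, 5))})


class TestSummarizePosterior:
    def test_quantile_rule_on_1_to_100(self):
        draws = np.arange(1.0, 101.0)
        lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
        assert med == pytest.approx(50.5)
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_constant_draws(self):
        post = make_posterior(
            beta=np.full((2, 7), 1.5), phi=0.2, sigma=0.5, a=np.full((1, 2), 2.0),
            w_asw=np.full((5, 5), 0.04), w_vpd=np.full((5, 5), 0.04),
        )
        s = summarize_posterior(post)
        row = s.loc["beta_untreated_BA"]
        assert row["median"] == row["ci_lo"] == row["ci_hi"] == 1.5


class TestPairwiseDifferences:
    def test_identical_draw_streams(self):
        post = make_posterior(
            beta=np.full((2, 7), 0.7), phi=0.0, sigma=1.0, a=np.zeros((1, 2)),
            w_asw=np.full((5, 5), 0.04), w_vpd=np.full((5, 5), 0.04),
        )
        d = pairwise_treatment_differences(post)
        assert (d["median"] == 0).all()
        assert not d["credible"].any()

    def test_constant_shift_flagged(self):
        beta = np.zeros((2, 7))
        beta[1] = 1.0  # treated = untreated + 1
        post = make_posterior(
            beta=beta, phi=0.0, sigma=1.0, a=np.zeros((1, 2)),
            w_asw=np.full((5, 5), 0.04), w_vpd=np.full((5, 5), 0.04),
        )
        d = pairwise_treatment_differences(post)
        assert (d["median"] == 1.0).all()
        assert (d["ci_lo"] == 1.0).all() and (d["ci_hi"] == 1.0).all()
        assert d["credible"].all()

    def test_quantiles_match_direct_subtraction(self, desk_fit):
        _, _, post = desk_fit
        d = pairwise_treatment_differences(post)
        delta = (post.beta[:, :, 1, 2] - post.beta[:, :, 0, 2]).ravel()
        assert d.loc["ASW", "median"] == pytest.approx(np.median(delta), abs=1e-12)
        assert d.loc["ASW", "ci_lo"] == pytest.approx(np.quantile(delta, 0.025), abs=1e-12)


class TestEffectSizes:
    def test_missing_stored_sds_rejected(self):
        from dendrosam.covariates import Standardizer

        design, beta, _ = make_flat_design(n=50, seed=4)
        design.standardizer = Standardizer()  # no stored statistics
        post = make_posterior(
            beta=np.vstack([beta, beta]), phi=0.0, sigma=1.0, a=np.zeros((1, 2)),
            w_asw=np.full((5, 5), 0.04), w_vpd=np.full((5, 5), 0.04),
        )
        with pytest.raises(ValueError, match="standardization"):
            effect_sizes(post, design)

    def test_unit_sd_covariate_effect_equals_beta(self):
        design, beta, _ = make_flat_design(n=5000, seed=4)
        post = make_posterior(
            beta=np.vstack([beta, beta]), phi=0.0, sigma=1.0, a=np.zeros((1, 2)),
            w_asw=np.full((5, 5), 0.04), w_vpd=np.full((5, 5), 0.04),
        )
        eff = effect_sizes(post, design)
        # BA is standardized-ish (iid N(0,1) draws): SD ~ 1 so effect ~ beta
        assert eff.loc["untreated_BA", "median"] == pytest.approx(
            beta[0] * np.std(design.ba), abs=1e-12
        )

    def test_brute_force_index_sd_oracle(self):
        design, beta, _ = make_flat_design(n=500, seed=5)
        rng = np.random.default_rng(6)
        w = rng.dirichlet(np.ones(25)).reshape(5, 5)
        post = make_posterior(
            beta=np.vstack([beta, beta]), phi=0.0, sigma=1.0, a=np.zeros((1, 2)),
            w_asw=w, w_vpd=np.full((5, 5), 0.04),
        )
        eff = effect_sizes(post, design)
        idx = np.array([
            sum(w[s, l] * design.cube_asw[i].reshape(5, 5)[s, l] for s in range(5) for l in range(5))
            for i in range(design.n_rows)
        ])
        assert eff.loc["treated_ASW", "median"] == pytest.approx(beta[2] * idx.std(), abs=1e-10)


class TestBayesianR2Rmse:
    def test_noise_free_perfect_fit(self):
        design, beta, X = make_flat_design(n=100, seed=7, sigma=0.0, intercept=2.0)
        post = make_posterior(
            beta=np.vstack([beta, beta]), phi=0.0, sigma=1e-9, a=np.full((1, 2), 2.0),
            w_asw=np.full((5, 5), 0.04), w_vpd=np.full((5, 5), 0.04),
        )
        r2, rmse = bayesian_r2_rmse(post, design)
        assert np.median(r2) > 0.999999
        assert rmse == pytest.approx(0.0, abs=1e-9)

    def test_intercept_only_r2_near_zero(self):
        design, beta, X = make_flat_design(n=100, seed=8, sigma=0.5)
        post = make_posterior(
            beta=np.zeros((2, 7)), phi=0.0, sigma=1.0, a=np.full((1, 2), 2.0),
            w_asw=np.full((5, 5), 0.04), w_vpd=np.full((5, 5), 0.04),
        )
        r2, _ = bayesian_r2_rmse(post, design)
        assert np.median(r2) == pytest.approx(0.0, abs=1e-9)

    def test_variance_ratio_oracle_small_design(self):
        design, beta, X = make_flat_design(n=20, seed=9)
        post = make_posterior(
            beta=np.vstack([beta, beta]), phi=0.1, sigma=0.8, a=np.full((1, 2), 1.0),
            w_asw=np.full((5, 5), 0.04), w_vpd=np.full((5, 5), 0.04),
        )
        r2, rmse = bayesian_r2_rmse(post, design)
        mu = 1.0 + X @ beta + 0.1 * design.prior_y
        expected = mu.var() / (mu.var() + 0.8**2)
        np.testing.assert_allclose(r2, expected, atol=1e-10)
        assert rmse == pytest.approx(np.sqrt(np.mean((design.y - mu) ** 2)), abs=1e-10)
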