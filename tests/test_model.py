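"""Model mathematics: antecedent index, mean function, log posterior."""

import numpy as np
import pytest
from scipy import stats

from dendrosam import (
    AntecedentWeights,
    CoefficientSet,
    InterceptHierarchy,
    Priors,
    SamParameters,
    antecedent_index,
    log_posterior,
    mean_function,
    yearly_weight_totals,
)
from conftest import make_flat_design


def simplex(rng, shape=(5, 5)):
    w = rng.gamma(1.0, size=shape)
    return w / w.sum()


class TestAntecedentIndex:
    def test_uniform_weights_give_grand_mean(self):
        X = np.arange(25.0).reshape(5, 5)
        w = AntecedentWeights.uniform("ASW")
        assert antecedent_index(w, X) == pytest.approx(X.mean())

    def test_one_hot_selects_cell(self):
        w = np.zeros((5, 5))
        w[1, 0] = 1.0  # spring, lag 0
        X = np.random.default_rng(0).normal(size=(5, 5))
        assert antecedent_index(AntecedentWeights("ASW", w), X) == pytest.approx(X[1, 0])

    def test_brute_force_double_sum(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            w = simplex(rng)
            X = rng.normal(size=(5, 5))
            brute = sum(w[s, l] * X[s, l] for s in range(5) for l in range(5))
            assert antecedent_index(AntecedentWeights("ASW", w), X) == pytest.approx(brute, abs=1e-12)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            antecedent_index(np.full((5, 5), 0.05), np.zeros((5, 5)))


class TestYearlyWeightTotals:
    def test_uniform_and_one_hot(self):
        np.testing.assert_allclose(yearly_weight_totals(np.full((5, 5), 0.04)), [0.2] * 5)
        w = np.zeros((5, 5))
        w[2, 0] = 1.0
        np.testing.assert_allclose(yearly_weight_totals(w), [1, 0, 0, 0, 0])

    def test_column_sum_oracle(self):
        rng = np.random.default_rng(2)
        w = simplex(rng)
        np.testing.assert_allclose(yearly_weight_totals(w), w.sum(axis=0), atol=1e-12)
        assert yearly_weight_totals(w).sum() == pytest.approx(1.0, abs=1e-12)


def toy_params(beta=0.5, phi=0.2, intercept=2.0, sigma=1.0, n_sites=1):
    a = np.full((n_sites, 2), intercept)
    return SamParameters(
        coef=CoefficientSet(np.full((2, 7), beta), phi, sigma),
        intercepts=InterceptHierarchy(a, np.zeros(1), np.zeros(1), 0.3, 0.3),
        w_asw=AntecedentWeights.uniform("ASW"),
        w_vpd=AntecedentWeights.uniform("VPD"),
    )


def one_row_design(ba=1.0, dbh=1.0, cube_val=1.0, prior=1.0, status=0):
    from dendrosam.covariates import Standardizer
    from dendrosam.design import ModelDesign

    return ModelDesign(
        y=np.array([0.0]), prior_y=np.array([prior]), ba=np.array([ba]),
        sqrt_dbh=np.array([dbh]), cube_asw=np.full((1, 25), cube_val),
        cube_vpd=np.full((1, 25), cube_val), status=np.array([status]),
        site_idx=np.array([0]), block_idx=np.array([0]), tree_idx=np.array([0]),
        years=np.array([2000]), site_labels=("s",), block_labels=("b",),
        tree_labels=("t",), standardizer=Standardizer(),
    )


class TestMeanFunction:
    def test_intercept_only(self):
        d = one_row_design(ba=0, dbh=0, cube_val=0, prior=0)
        p = toy_params(beta=0.5, phi=0.2, intercept=2.0)
        assert mean_function(d, p)[0] == pytest.approx(2.0)

    def test_hand_summed_toy_row(self):
        # BA=1, dbh=1, both indices 1 -> all 7 covariates equal 1
        d = one_row_design()
        p = toy_params(beta=0.5, phi=0.2, intercept=2.0)
        assert mean_function(d, p)[0] == pytest.approx(2.0 + 0.5 * 7 + 0.2)

    def test_status_switches_coefficient_set(self):
        d = one_row_design(status=1)
        beta = np.zeros((2, 7))
        beta[0] = 9.9  # untreated set must NOT be used
        p = SamParameters(
            coef=CoefficientSet(beta, 0.2, 1.0),
            intercepts=InterceptHierarchy(np.array([[1.0, 3.0]]), np.zeros(1), np.zeros(1), 0.3, 0.3),
            w_asw=AntecedentWeights.uniform("ASW"),
            w_vpd=AntecedentWeights.uniform("VPD"),
        )
        assert mean_function(d, p)[0] == pytest.approx(3.0 + 0.2 * 1.0)

    def test_dimension_mismatch_rejected(self):
        d = one_row_design()
        p = toy_params(n_sites=3)
        with pytest.raises(ValueError, match="sites"):
            mean_function(d, p)


class TestLogPosterior:
    def test_single_observation_closed_form(self):
        d = one_row_design(ba=0, dbh=0, cube_val=0, prior=0)
        p = toy_params(beta=0.0, phi=0.0, intercept=0.0, sigma=1.0)
        lp = log_posterior(p, d)
        # likelihood part is the standard normal logpdf at y=0, mu=0
        lik = -0.5 * np.log(2 * np.pi)
        prior_part = lp - lik
        p2 = toy_params(beta=0.0, phi=0.0, intercept=0.0, sigma=1.0)
        d2 = one_row_design(ba=0, dbh=0, cube_val=0, prior=0)
        d2.y[0] = 2.0  # same priors, different residual
        assert log_posterior(p2, d2) - prior_part == pytest.approx(lik - 2.0)

    def test_out_of_support(self):
        d = one_row_design()
        p = toy_params(sigma=0.0)
        assert log_posterior(p, d) == -np.inf

    def test_naive_density_summation_oracle(self):
        """Row-wise scipy density sums must match the vectorized computation."""
        design, beta, X = make_flat_design(n=10, seed=3)
        rng = np.random.default_rng(4)
        w_a, w_v = simplex(rng), simplex(rng)
        params = SamParameters(
            coef=CoefficientSet(np.vstack([beta, beta * 0.5]), 0.1, 0.7),
            intercepts=InterceptHierarchy(np.array([[1.5, 2.5]]), rng.normal(size=1), rng.normal(size=1), 0.4, 0.6),
            w_asw=AntecedentWeights("ASW", w_a),
            w_vpd=AntecedentWeights("VPD", w_v),
        )
        pr = Priors()
        mu = mean_function(design, params)
        naive = 0.0
        for i in range(design.n_rows):
            naive += stats.norm.logpdf(design.y[i], mu[i], 0.7)
        naive += stats.norm.logpdf(params.coef.beta, scale=pr.coef_sd).sum()
        naive += stats.norm.logpdf(0.1, scale=pr.coef_sd)
        naive += stats.norm.logpdf(params.intercepts.a, scale=pr.intercept_sd).sum()
        naive += stats.norm.logpdf(params.intercepts.d_block, scale=0.4).sum()
        naive += stats.norm.logpdf(params.intercepts.d_tree, scale=0.6).sum()
        for s in (0.7, 0.4, 0.6):
            naive += np.log(2.0) + stats.cauchy.logpdf(s, scale=pr.half_cauchy_scale)
        for w in (w_a, w_v):
            naive += stats.dirichlet.logpdf(w.ravel(), np.ones(25))
        assert log_posterior(params, design) == pytest.approx(naive, abs=1e-10)

    def test_doubling_identical_observations_doubles_likelihood(self):
        d1 = one_row_design(ba=0, dbh=0, cube_val=0, prior=0)
        p = toy_params(beta=0.0, phi=0.0, intercept=0.5, sigma=1.0)
        lp1 = log_posterior(p, d1)
        from dendrosam.covariates import Standardizer
        from dendrosam.design import ModelDesign

        d2 = ModelDesign(
            y=np.zeros(2), prior_y=np.zeros(2), ba=np.zeros(2), sqrt_dbh=np.zeros(2),
            cube_asw=np.zeros((2, 25)), cube_vpd=np.zeros((2, 25)),
            status=np.zeros(2, dtype=int), site_idx=np.zeros(2, dtype=int),
            block_idx=np.zeros(2, dtype=int), tree_idx=np.zeros(2, dtype=int),
            years=np.full(2, 2000), site_labels=("s",), block_labels=("b",),
            tree_labels=("t",), standardizer=Standardizer(),
        )
        lp2 = log_posterior(p, d2)
        lik1 = stats.norm.logpdf(0.0, 0.5, 1.0)
        assert lp2 - lp1 == pytest.approx(lik1, abs=1e-10)
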