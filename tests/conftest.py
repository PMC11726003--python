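import numpy as np
import pytest

from dendrosam.covariates import Standardizer
from dendrosam.design import ModelDesign
from dendrosam.posterior import Posterior


def make_flat_design(n=200, seed=0, beta=None, sigma=0.5, intercept=2.0,
                     w_asw=None, w_vpd=None, phi=0.0):
    """Single-site, single-status synthetic design with iid covariates.

    A minimal linear-model testbed for the sampler: all rows untreated,
    flat nesting (one site/block/tree), Gaussian cube cells.
    """
    rng = np.random.default_rng(seed)
    cube_a = rng.standard_normal((n, 25))
    cube_v = rng.standard_normal((n, 25))
    wa = np.full(25, 0.04) if w_asw is None else np.asarray(w_asw).ravel()
    wv = np.full(25, 0.04) if w_vpd is None else np.asarray(w_vpd).ravel()
    ba = rng.standard_normal(n)
    dbh = rng.standard_normal(n)
    prior = rng.standard_normal(n)
    ia, iv = cube_a @ wa, cube_v @ wv
    if beta is None:
        beta = np.array([-0.3, 0.4, 0.6, -0.5, 0.05, -0.1, 0.15])
    X = np.column_stack([ba, dbh, ia, iv, ia * dbh, iv * dbh, ia * iv])
    y = intercept + X @ beta + phi * prior + sigma * rng.standard_normal(n)
    std = Standardizer()
    std.means = {"ba": 0.0, "sqrt_dbh": 0.0, "asw_cube": 0.0, "vpd_cube": 0.0}
    std.sds = {"ba": 1.0, "sqrt_dbh": 1.0, "asw_cube": 1.0, "vpd_cube": 1.0}
    return ModelDesign(
        y=y, prior_y=prior, ba=ba, sqrt_dbh=dbh, cube_asw=cube_a, cube_vpd=cube_v,
        status=np.zeros(n, dtype=int), site_idx=np.zeros(n, dtype=int),
        block_idx=np.zeros(n, dtype=int), tree_idx=np.zeros(n, dtype=int),
        years=np.full(n, 2000), site_labels=("s1",), block_labels=("b1",),
        tree_labels=("t1",), standardizer=std,
    ), beta, X


def make_posterior(beta, phi, sigma, a, w_asw, w_vpd, n_chains=2, n_kept=50,
                   d_block=None, d_tree=None, tau=0.3):
    """Posterior whose every draw equals the given parameter point."""
    C, K = n_chains, n_kept
    nb = 0 if d_block is None else len(d_block)
    nt = 0 if d_tree is None else len(d_tree)
    a = np.asarray(a, dtype=float)
    post = Posterior(
        beta=np.tile(np.asarray(beta, dtype=float), (C, K, 1, 1)),
        phi=np.full((C, K), phi),
        sigma=np.full((C, K), sigma),
        tau_block=np.full((C, K), tau),
        tau_tree=np.full((C, K), tau),
        a=np.tile(a, (C, K, 1, 1)),
        d_block=np.tile(np.zeros(nb) if d_block is None else np.asarray(d_block), (C, K, 1)),
        d_tree=np.tile(np.zeros(nt) if d_tree is None else np.asarray(d_tree), (C, K, 1)),
        w_asw=np.tile(np.asarray(w_asw, dtype=float), (C, K, 1, 1)),
        w_vpd=np.tile(np.asarray(w_vpd, dtype=float), (C, K, 1, 1)),
        n_chains=C, n_iter=K + 1, n_burnin=1, seed=0, config_hash="fixed",
        site_labels=tuple(f"S{i+1}" for i in range(a.shape[0])),
    )
    return post


@pytest.fixture(scope="session")
def desk_dataset():
    """One desk-scale synthetic dataset with truth, shared across tests."""
    from dendrosam import SimConfig, generate_dataset

    return generate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def desk_fit(desk_dataset):
    """A short (but converged-ish) fit of the shared desk dataset."""
    from dendrosam import MCMCConfig, fit_mcmc

    design, truth = desk_dataset
    post = fit_mcmc(design, MCMCConfig(n_chains=2, n_iter=1500, n_burnin=500, seed=42))
    return design, truth, post
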