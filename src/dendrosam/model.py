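"""The hierarchical stochastic-antecedent growth model.

Power-transformed BAI ``y[i]`` for tree-year row *i* is modeled as

    y[i] ~ Normal(mu[i], sigma^2)
    mu[i] = a[site(i), status(i)] + d_block[block(i)] + d_tree[tree(i)]
            + beta[status(i)] . x[i] + phi * y_prior[i]

with the covariate vector

    x = (BA, sqrt_dbh, ASW_ant, VPD_ant,
         ASW_ant*sqrt_dbh, VPD_ant*sqrt_dbh, ASW_ant*VPD_ant)

where the antecedent indices are simplex-weighted averages of the 5
season × 5 lag-year climate cubes,

    ASW_ant[i] = sum_{s,l} w_asw[s,l] * ASW_cube[i, s, l]     (same for VPD),

with one weight matrix per climate variable shared across treatment
statuses.  The seven covariate coefficients switch with the ring's
treatment status; the autoregressive coefficient ``phi`` and the
residual SD ``sigma`` are shared.  Intercepts carry the nested design:
site × status fixed levels plus block and tree deviations with SDs
``tau_block`` and ``tau_tree``.

Priors (weakly informative): coefficients and intercept levels
Normal(0, 100²); SDs half-Cauchy(scale 5); each weight matrix
Dirichlet(1, ..., 1) over its 25 cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import COVARIATE_NAMES, ModelDesign

__all__ = [
    "AntecedentWeights",
    "CoefficientSet",
    "InterceptHierarchy",
    "SamParameters",
    "Priors",
    "antecedent_index",
    "mean_function",
    "log_posterior",
]

_SIMPLEX_TOL = 1e-8


@dataclass(frozen=True)
class AntecedentWeights:
    """5×5 simplex weight matrix (season × lag) for one climate variable."""

    variable: str  # "ASW" | "VPD"
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.shape != (5, 5):
            raise ValueError("weights must be a 5x5 matrix")
        if np.any(w < 0) or abs(w.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("weights must be non-negative and sum to 1")

    @classmethod
    def uniform(cls, variable: str) -> "AntecedentWeights":
        return cls(variable, np.full((5, 5), 1.0 / 25.0))


@dataclass(frozen=True)
class CoefficientSet:
    """Status-specific covariate effects plus shared AR and residual terms.

    ``beta`` has shape (2, 7): rows untreated / treated, columns in the
    order of :data:`dendrosam.design.COVARIATE_NAMES`.
    """

    beta: np.ndarray
    phi: float
    sigma: float

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "beta", beta)
        if beta.shape != (2, len(COVARIATE_NAMES)):
            raise ValueError(f"beta must have shape (2, {len(COVARIATE_NAMES)})")
        if not np.all(np.isfinite(beta)) or not np.isfinite(self.phi):
            raise ValueError("coefficients must be finite")
        # sigma = 0 is allowed for noise-free generative runs; the posterior
        # density is -inf there (outside the support of the half-Cauchy prior)
        if not (self.sigma >= 0):
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class InterceptHierarchy:
    """Site×status intercept levels plus block and tree deviations."""

    a: np.ndarray  # (n_sites, 2)
    d_block: np.ndarray
    d_tree: np.ndarray
    tau_block: float
    tau_tree: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "d_block", np.asarray(self.d_block, dtype=float))
        object.__setattr__(self, "d_tree", np.asarray(self.d_tree, dtype=float))
        if self.a.ndim != 2 or self.a.shape[1] != 2:
            raise ValueError("a must have shape (n_sites, 2)")
        if not (self.tau_block >= 0 and self.tau_tree >= 0):
            raise ValueError("tau_block and tau_tree must be >= 0")


@dataclass(frozen=True)
class SamParameters:
    """Complete parameter set of the reference model."""

    coef: CoefficientSet
    intercepts: InterceptHierarchy
    w_asw: AntecedentWeights
    w_vpd: AntecedentWeights


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the weakly informative priors."""

    coef_sd: float = 100.0
    intercept_sd: float = 100.0
    half_cauchy_scale: float = 5.0
    dirichlet_conc: float = 1.0


def antecedent_index(w: AntecedentWeights | np.ndarray, X: np.ndarray) -> float | np.ndarray:
    """Simplex-weighted average of a seasonal-lag matrix (or stack of them).

    ``X`` may be a single 5×5 matrix or an (n, 25) / (n, 5, 5) stack; the
    result is a scalar or length-n vector, ``sum_{s,l} w[s,l] X[s,l]``.
    """
    wm = w.w if isinstance(w, AntecedentWeights) else np.asarray(w, dtype=float)
    if np.any(wm < 0) or abs(wm.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError("weights are off the simplex")
    flat = wm.ravel()
    X = np.asarray(X, dtype=float)
    if X.shape == (5, 5):
        return float(X.ravel() @ flat)
    return X.reshape(X.shape[0], -1) @ flat


def _covariate_matrix(design: ModelDesign, w_asw, w_vpd) -> np.ndarray:
    """(n, 7) covariate values in COVARIATE_NAMES order for given weights."""
    idx_a = antecedent_index(w_asw, design.cube_asw)
    idx_v = antecedent_index(w_vpd, design.cube_vpd)
    return np.column_stack(
        [
            design.ba,
            design.sqrt_dbh,
            idx_a,
            idx_v,
            idx_a * design.sqrt_dbh,
            idx_v * design.sqrt_dbh,
            idx_a * idx_v,
        ]
    )


def mean_function(design: ModelDesign, params: SamParameters) -> np.ndarray:
    """Expected transformed BAI per design row under ``params``.

    The status of each row selects which of the two coefficient sets
    applies; antecedent indices are computed from the shared weights.
    """
    ih = params.intercepts
    if ih.a.shape[0] != design.n_sites:
        raise ValueError("intercept matrix does not match number of sites")
    if ih.d_block.size != design.n_blocks or ih.d_tree.size != design.n_trees:
        raise ValueError("block/tree effect vectors do not match the design")
    X = _covariate_matrix(design, params.w_asw, params.w_vpd)
    beta_rows = params.coef.beta[design.status]  # (n, 7)
    mu = (
        ih.a[design.site_idx, design.status]
        + ih.d_block[design.block_idx]
        + ih.d_tree[design.tree_idx]
        + np.einsum("ij,ij->i", X, beta_rows)
        + params.coef.phi * design.prior_y
    )
    return mu


def log_posterior(params: SamParameters, design: ModelDesign, priors: Priors | None = None) -> float:
    """Unnormalized log posterior density; ``-inf`` outside the support."""
    priors = priors or Priors()
    coef, ih = params.coef, params.intercepts
    if not (coef.sigma > 0 and ih.tau_block > 0 and ih.tau_tree > 0):
        return -np.inf
    for w in (params.w_asw, params.w_vpd):
        if np.any(w.w < 0) or abs(w.w.sum() - 1.0) > _SIMPLEX_TOL:
            return -np.inf
    mu = mean_function(design, params)
    n = design.n_rows
    resid = design.y - mu
    loglik = -0.5 * n * np.log(2 * np.pi * coef.sigma**2) - 0.5 * resid @ resid / coef.sigma**2

    lp = loglik
    lp += stats.norm.logpdf(coef.beta, scale=priors.coef_sd).sum()
    lp += stats.norm.logpdf(coef.phi, scale=priors.coef_sd)
    lp += stats.norm.logpdf(ih.a, scale=priors.intercept_sd).sum()
    lp += stats.norm.logpdf(ih.d_block, scale=ih.tau_block).sum()
    lp += stats.norm.logpdf(ih.d_tree, scale=ih.tau_tree).sum()
    # half-Cauchy(scale) on SDs: log 2 + Cauchy density on the positive half
    for s in (coef.sigma, ih.tau_block, ih.tau_tree):
        lp += np.log(2.0) + stats.cauchy.logpdf(s, scale=priors.half_cauchy_scale)
    # symmetric Dirichlet over each 25-cell simplex
    a = priors.dirichlet_conc
    for w in (params.w_asw, params.w_vpd):
        with np.errstate(divide="ignore"):
            lp += stats.dirichlet.logpdf(
                np.clip(w.w.ravel(), 1e-300, None), np.full(25, a)
            )
    return float(lp)
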