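"""Blocked Gibbs / Metropolis sampler for the hierarchical SAM regression.

Conditional on the antecedent weights, every location parameter of the
model (site × status intercepts, block and tree deviations, the fourteen
status-specific covariate effects and the AR coefficient) is jointly
Gaussian, so the sampler draws them in a single multivariate-normal block
from the exact full conditional — this joint draw also delivers what
hierarchical centering is meant to buy in one-at-a-time samplers
(identifiable intercepts, good mixing of the nested levels).  The scale
parameters (residual sigma and the two deviation SDs) get stepping-out
slice updates on the log scale under their half-Cauchy priors.  Each 5×5
weight matrix is updated by adaptive single-cell Metropolis moves on a
softmax parameterization; because the likelihood is a quadratic form in
the weight vector once everything else is held fixed, the 24 cell moves
per sweep cost 25²-sized arithmetic each, with the quadratic form
pre-assembled once per iteration.  Proposal scales adapt during burn-in
only and are frozen afterwards, so the retained chain is a valid
fixed-kernel Markov chain.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .design import COVARIATE_NAMES, ModelDesign
from .model import AntecedentWeights, Priors
from .posterior import Posterior

__all__ = ["MCMCConfig", "fit_mcmc"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    ``n_iter`` counts total iterations per chain including burn-in;
    ``n_burnin`` draws are discarded.  ``fixed_weights`` pins both weight
    matrices (no weight updates), ``fix_phi`` removes the AR coefficient
    from sampling and holds it at the given value, and
    ``flat_intercepts`` collapses the intercept hierarchy to a single
    global intercept (used by the conjugate-limit check).  With
    ``likelihood=False`` the sampler targets the prior alone.
    """

    n_chains: int = 3
    n_iter: int = 20000
    n_burnin: int = 1000
    seed: int = 0
    thin: int = 1
    likelihood: bool = True
    fixed_weights: tuple[AntecedentWeights, AntecedentWeights] | None = None
    init_weights: tuple[AntecedentWeights, AntecedentWeights] | None = None
    fix_phi: float | None = None
    flat_intercepts: bool = False
    priors: Priors = field(default_factory=Priors)
    n_weight_sweeps: int = 4  # Metropolis sweeps (random scan) per weight matrix per iteration
    adapt_interval: int = 25
    init_jitter: float = 0.1

    def hash(self) -> str:
        return hashlib.md5(repr(self).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# weight-update kernel: single-cell Metropolis on softmax coordinates

def _eta_logp_py(eta, Aq, bq, conc, w):
    m = eta.max()
    np.exp(eta - m, out=w)
    w /= w.sum()
    lp = conc * np.log(w).sum()
    lp += bq @ w - 0.5 * (w @ (Aq @ w))
    return lp


@njit(cache=True)
def _eta_logp_nb(eta, Aq, bq, conc, w):  # pragma: no cover - compiled
    K = eta.shape[0]
    m = eta[0]
    for k in range(1, K):
        if eta[k] > m:
            m = eta[k]
    s = 0.0
    for k in range(K):
        w[k] = math.exp(eta[k] - m)
        s += w[k]
    lp = 0.0
    for k in range(K):
        w[k] /= s
        lp += conc * math.log(w[k])
    for k in range(K):
        t = 0.0
        for l in range(K):
            t += Aq[k, l] * w[l]
        lp += bq[k] * w[k] - 0.5 * w[k] * t
    return lp


@njit(cache=True)
def _weight_sweep_nb(eta, scales, Aq, bq, conc, z, u, acc, order):  # pragma: no cover
    K = eta.shape[0]
    w = np.empty(K)
    logp = _eta_logp_nb(eta, Aq, bq, conc, w)
    for i in range(K - 1):
        j = order[i]
        old = eta[j]
        eta[j] = old + scales[j] * z[i]
        lp2 = _eta_logp_nb(eta, Aq, bq, conc, w)
        if math.log(u[i]) < lp2 - logp:
            logp = lp2
            acc[j] += 1
        else:
            eta[j] = old


def _weight_sweep_py(eta, scales, Aq, bq, conc, z, u, acc, order):
    K = eta.shape[0]
    w = np.empty(K)
    logp = _eta_logp_py(eta, Aq, bq, conc, w)
    for i in range(K - 1):
        j = order[i]
        old = eta[j]
        eta[j] = old + scales[j] * z[i]
        lp2 = _eta_logp_py(eta, Aq, bq, conc, w)
        if math.log(u[i]) < lp2 - logp:
            logp = lp2
            acc[j] += 1
        else:
            eta[j] = old


_weight_sweep = _weight_sweep_nb if _HAVE_NUMBA else _weight_sweep_py


def _softmax(eta: np.ndarray) -> np.ndarray:
    e = np.exp(eta - eta.max())
    return e / e.sum()


# ---------------------------------------------------------------------------
# scale updates: stepping-out slice sampler on the log scale


def _slice_logscale(logf, x0: float, rng, width: float = 1.0, max_steps: int = 50) -> float:
    u0 = math.log(x0)
    y = logf(u0) - rng.exponential()
    L = u0 - width * rng.random()
    R = L + width
    for _ in range(max_steps):
        if logf(L) <= y:
            break
        L -= width
    for _ in range(max_steps):
        if logf(R) <= y:
            break
        R += width
    for _ in range(200):
        u1 = rng.uniform(L, R)
        if logf(u1) > y:
            return math.exp(u1)
        if u1 < u0:
            L = u1
        else:
            R = u1
    return x0  # numerically stuck: keep current value


def _make_scale_logf(n_eff: float, ss: float, hc_scale: float):
    def logf(u: float) -> float:
        x2 = math.exp(2 * u)
        return (
            -n_eff * u
            - 0.5 * ss / x2
            - math.log1p(x2 / hc_scale**2)
            + u  # Jacobian of the log transform
        )

    return logf


# ---------------------------------------------------------------------------


class _Layout:
    """Column layout of the joint Gaussian block."""

    def __init__(self, design: ModelDesign, cfg: MCMCConfig):
        self.flat = cfg.flat_intercepts
        self.sample_phi = cfg.fix_phi is None
        n_cov = len(COVARIATE_NAMES)
        p = 0
        if self.flat:
            self.sl_a = slice(0, 1)
            p = 1
        else:
            self.n_a = design.n_sites * 2
            self.sl_a = slice(0, self.n_a)
            p = self.n_a
            self.sl_block = slice(p, p + design.n_blocks)
            p += design.n_blocks
            self.sl_tree = slice(p, p + design.n_trees)
            p += design.n_trees
        self.sl_beta = slice(p, p + 2 * n_cov)
        p += 2 * n_cov
        if self.sample_phi:
            self.i_phi = p
            p += 1
        self.p = p

    def beta_of(self, theta: np.ndarray) -> np.ndarray:
        return theta[self.sl_beta].reshape(2, len(COVARIATE_NAMES))


def _build_X(design: ModelDesign, layout: _Layout, idx_a, idx_v):
    n = design.n_rows
    X = np.zeros((n, layout.p))
    rows = np.arange(n)
    if layout.flat:
        X[:, 0] = 1.0
    else:
        X[rows, design.site_idx * 2 + design.status] = 1.0
        X[rows, layout.sl_block.start + design.block_idx] = 1.0
        X[rows, layout.sl_tree.start + design.tree_idx] = 1.0
    _set_beta_columns(X, design, layout, idx_a, idx_v)
    if layout.sample_phi:
        X[:, layout.i_phi] = design.prior_y
    return X


_ANT_COVS = (2, 3, 4, 5, 6)  # covariate slots that depend on the weights


def _cov_columns(design: ModelDesign, idx_a, idx_v) -> dict[int, np.ndarray]:
    return {
        0: design.ba,
        1: design.sqrt_dbh,
        2: idx_a,
        3: idx_v,
        4: idx_a * design.sqrt_dbh,
        5: idx_v * design.sqrt_dbh,
        6: idx_a * idx_v,
    }


def _set_beta_columns(X, design, layout, idx_a, idx_v, only_antecedent=False):
    cols = _cov_columns(design, idx_a, idx_v)
    n_cov = len(COVARIATE_NAMES)
    for s, mask in enumerate((design.status == 0, design.status == 1)):
        m = mask.astype(float)
        for c, col in cols.items():
            if only_antecedent and c not in _ANT_COVS:
                continue
            X[:, layout.sl_beta.start + s * n_cov + c] = col * m


def fit_mcmc(design: ModelDesign, config: MCMCConfig | None = None, **overrides) -> Posterior:
    """Run the sampler and return retained post-burn-in draws.

    Chains run sequentially with independent seed streams spawned from
    ``config.seed``; the same seed and configuration reproduce the draws
    exactly.
    """
    cfg = config or MCMCConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    if cfg.n_burnin >= cfg.n_iter:
        raise ValueError("n_burnin must be < n_iter")
    if cfg.likelihood and not cfg.flat_intercepts:
        _check_cells(design)

    n_cov = len(COVARIATE_NAMES)
    layout = _Layout(design, cfg)
    kept = (cfg.n_iter - cfg.n_burnin) // cfg.thin
    C = cfg.n_chains
    S = 1 if cfg.flat_intercepts else design.n_sites
    a_cols = 1 if cfg.flat_intercepts else 2
    B = 0 if cfg.flat_intercepts else design.n_blocks
    T = 0 if cfg.flat_intercepts else design.n_trees

    store = {
        "beta": np.empty((C, kept, 2, n_cov)),
        "phi": np.empty((C, kept)),
        "sigma": np.empty((C, kept)),
        "tau_block": np.full((C, kept), np.nan),
        "tau_tree": np.full((C, kept), np.nan),
        "a": np.empty((C, kept, S, a_cols)),
        "d_block": np.empty((C, kept, B)),
        "d_tree": np.empty((C, kept, T)),
        "w_asw": np.empty((C, kept, 5, 5)),
        "w_vpd": np.empty((C, kept, 5, 5)),
    }

    seeds = np.random.SeedSequence(cfg.seed).spawn(C)
    for ci in range(C):
        rng = np.random.default_rng(seeds[ci])
        _run_chain(design, cfg, layout, rng, store, ci, kept)

    return Posterior(
        **store,
        n_chains=C,
        n_iter=cfg.n_iter,
        n_burnin=cfg.n_burnin,
        seed=cfg.seed,
        config_hash=cfg.hash(),
        site_labels=("all",) if cfg.flat_intercepts else design.site_labels,
    )


def _check_cells(design: ModelDesign) -> None:
    for si in range(design.n_sites):
        for s in (0, 1):
            if not np.any((design.site_idx == si) & (design.status == s)):
                warnings.warn(
                    f"site {design.site_labels[si]!r} has no rows with status {s}; "
                    "its intercept for that status is prior-identified only"
                )


def _run_chain(design: ModelDesign, cfg: MCMCConfig, layout: _Layout, rng, store, ci, kept):
    pr = cfg.priors
    n = design.n_rows
    n_cov = len(COVARIATE_NAMES)
    like = 1.0 if cfg.likelihood else 0.0
    sample_w = cfg.fixed_weights is None

    # --- weight state
    if sample_w:
        if cfg.init_weights is not None:
            eta_a = np.log(np.clip(cfg.init_weights[0].w.ravel(), 1e-8, None))
            eta_v = np.log(np.clip(cfg.init_weights[1].w.ravel(), 1e-8, None))
            eta_a -= eta_a[24]
            eta_v -= eta_v[24]
        else:
            eta_a = 0.01 * rng.standard_normal(25)
            eta_v = 0.01 * rng.standard_normal(25)
            eta_a[24] = eta_v[24] = 0.0
        w_a, w_v = _softmax(eta_a), _softmax(eta_v)
        scales_a = np.full(24, 0.5)
        scales_v = np.full(24, 0.5)
        acc_a = np.zeros(24)
        acc_v = np.zeros(24)
    else:
        w_a = cfg.fixed_weights[0].w.ravel().copy()
        w_v = cfg.fixed_weights[1].w.ravel().copy()
    idx_a = design.cube_asw @ w_a
    idx_v = design.cube_vpd @ w_v

    y_eff = design.y if cfg.fix_phi is None else design.y - cfg.fix_phi * design.prior_y
    X = _build_X(design, layout, idx_a, idx_v)

    # prior precision of the joint Gaussian block
    prior_prec = np.empty(layout.p)
    prior_prec[layout.sl_a] = 1.0 / pr.intercept_sd**2
    prior_prec[layout.sl_beta] = 1.0 / pr.coef_sd**2
    if layout.sample_phi:
        prior_prec[layout.i_phi] = 1.0 / pr.coef_sd**2

    sigma, tau_b, tau_c = 1.0, 0.5, 0.5

    # --- initialization with jittered retries
    theta = None
    for attempt in range(100):
        XtX = X.T @ X
        Xty = X.T @ y_eff
        ridge = XtX * like + np.eye(layout.p)
        try:
            theta0 = np.linalg.solve(ridge, Xty * like)
        except np.linalg.LinAlgError:
            theta0 = np.zeros(layout.p)
        theta0 = theta0 + cfg.init_jitter * rng.standard_normal(layout.p)
        resid = y_eff - X @ theta0
        if np.all(np.isfinite(resid)):
            theta = theta0
            sigma = max(float(resid.std()), 0.05) if cfg.likelihood else 1.0
            break
    if theta is None:
        raise RuntimeError("non-finite state at initialization after 100 jittered retries")

    xtx_dirty = True
    XtX = Xty = None
    hc = pr.half_cauchy_scale
    kept_i = 0
    for it in range(cfg.n_iter):
        # ---- joint Gaussian block: intercepts, deviations, betas, phi
        if xtx_dirty:
            XtX = X.T @ X
            Xty = X.T @ y_eff
            xtx_dirty = False
        prec = prior_prec.copy()
        if not layout.flat:
            prec[layout.sl_block] = 1.0 / tau_b**2
            prec[layout.sl_tree] = 1.0 / tau_c**2
        lam = (XtX * (like / sigma**2)) + np.diag(prec)
        chol = cho_factor(lam, lower=True)
        mean = cho_solve(chol, Xty * (like / sigma**2))
        z = rng.standard_normal(layout.p)
        theta = mean + solve_triangular(chol[0], z, lower=True, trans="T")
        resid = y_eff - X @ theta

        # ---- scale parameters
        ss = float(resid @ resid) * like
        sigma = _slice_logscale(_make_scale_logf(n * like, ss, hc), sigma, rng)
        if not layout.flat:
            db = theta[layout.sl_block]
            dt = theta[layout.sl_tree]
            tau_b = _slice_logscale(_make_scale_logf(db.size, float(db @ db), hc), tau_b, rng)
            tau_c = _slice_logscale(_make_scale_logf(dt.size, float(dt @ dt), hc), tau_c, rng)

        # ---- antecedent weights
        beta = layout.beta_of(theta)
        if sample_w:
            beta_row = beta[design.status]  # (n, 7)
            conc = pr.dirichlet_conc
            # ASW block: likelihood is quadratic in w_a given everything else
            g = beta_row[:, 2] + beta_row[:, 4] * design.sqrt_dbh + beta_row[:, 6] * idx_v
            r0 = resid + g * idx_a
            G = design.cube_asw * g[:, None]
            Aq = (G.T @ G) * (like / sigma**2)
            bq = (G.T @ r0) * (like / sigma**2)
            for _ in range(cfg.n_weight_sweeps):
                _weight_sweep(eta_a, scales_a, Aq, bq, conc, rng.standard_normal(24),
                              rng.random(24), acc_a, rng.permutation(24))
            w_a = _softmax(eta_a)
            idx_a = design.cube_asw @ w_a
            resid = r0 - g * idx_a
            # VPD block
            g = beta_row[:, 3] + beta_row[:, 5] * design.sqrt_dbh + beta_row[:, 6] * idx_a
            r0 = resid + g * idx_v
            G = design.cube_vpd * g[:, None]
            Aq = (G.T @ G) * (like / sigma**2)
            bq = (G.T @ r0) * (like / sigma**2)
            for _ in range(cfg.n_weight_sweeps):
                _weight_sweep(eta_v, scales_v, Aq, bq, conc, rng.standard_normal(24),
                              rng.random(24), acc_v, rng.permutation(24))
            w_v = _softmax(eta_v)
            idx_v = design.cube_vpd @ w_v
            _set_beta_columns(X, design, layout, idx_a, idx_v, only_antecedent=True)
            xtx_dirty = True

            if it < cfg.n_burnin and (it + 1) % cfg.adapt_interval == 0:
                for scales, acc in ((scales_a, acc_a), (scales_v, acc_v)):
                    rate = acc / (cfg.adapt_interval * cfg.n_weight_sweeps)
                    scales *= np.exp(0.66 * (rate - 0.44))
                    np.clip(scales, 1e-3, 20.0, out=scales)
                    acc[:] = 0.0

        # ---- store
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0 and kept_i < kept:
            store["beta"][ci, kept_i] = beta
            store["phi"][ci, kept_i] = theta[layout.i_phi] if layout.sample_phi else cfg.fix_phi
            store["sigma"][ci, kept_i] = sigma
            if not layout.flat:
                store["tau_block"][ci, kept_i] = tau_b
                store["tau_tree"][ci, kept_i] = tau_c
                store["a"][ci, kept_i] = theta[layout.sl_a].reshape(design.n_sites, 2)
                store["d_block"][ci, kept_i] = theta[layout.sl_block]
                store["d_tree"][ci, kept_i] = theta[layout.sl_tree]
            else:
                store["a"][ci, kept_i] = theta[layout.sl_a].reshape(1, 1)
            store["w_asw"][ci, kept_i] = w_a.reshape(5, 5)
            store["w_vpd"][ci, kept_i] = w_v.reshape(5, 5)
            kept_i += 1
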