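"""Posterior summaries: convergence, intervals, contrasts, fit statistics.

Point estimates are posterior medians; intervals are equal-tailed 95%
credible intervals computed with NumPy's default (linear-interpolation)
quantile rule.  Convergence is checked with the split-chain
Gelman–Rubin statistic: each chain is halved, and
R-hat = sqrt(((m-1)/m * W + B/m) / W) with within-half variance W and
between-half variance B over the split sequences of length m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import COVARIATE_NAMES, STATUS_LABELS, ModelDesign
from .model import antecedent_index
from .posterior import Posterior, scalar_draws

__all__ = [
    "gelman_rubin",
    "summarize_posterior",
    "pairwise_treatment_differences",
    "effect_sizes",
    "bayesian_r2_rmse",
    "median_predictions",
    "yearly_weight_totals",
    "FitSummary",
    "fit_summary",
]

RHAT_THRESHOLD = 1.05  # convergence pass criterion


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one (C, K) array."""
    C, K = draws.shape
    m = K // 2
    halves = np.concatenate([draws[:, :m], draws[:, m : 2 * m]], axis=0)  # (2C, m)
    W = halves.var(axis=1, ddof=1).mean()
    B = m * halves.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (m - 1) / m * W + B / m
    return float(np.sqrt(var_plus / W))


def gelman_rubin(post: Posterior | dict[str, np.ndarray]) -> pd.Series:
    """R-hat per monitored scalar parameter.

    Requires at least 2 chains and 10 post-burn-in draws per chain.
    """
    draws = scalar_draws(post) if isinstance(post, Posterior) else dict(post)
    some = next(iter(draws.values()))
    if some.shape[0] < 2:
        raise ValueError("Gelman-Rubin diagnostic requires >= 2 chains")
    if some.shape[1] < 10:
        raise ValueError("Gelman-Rubin diagnostic requires >= 10 draws per chain")
    return pd.Series({name: _split_rhat(d) for name, d in draws.items()}, name="rhat")


def _median_ci(x: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return float(med), float(lo), float(hi)


def summarize_posterior(post: Posterior) -> pd.DataFrame:
    """Median, equal-tailed 95% CrI and R-hat per monitored parameter."""
    rhat = gelman_rubin(post)
    rows = {}
    for name, d in scalar_draws(post).items():
        med, lo, hi = _median_ci(d.ravel())
        rows[name] = {"median": med, "ci_lo": lo, "ci_hi": hi, "rhat": rhat[name]}
    return pd.DataFrame(rows).T


def pairwise_treatment_differences(post: Posterior) -> pd.DataFrame:
    """Treated-minus-untreated coefficient contrasts, per covariate.

    ``credible`` flags contrasts whose 95% CrI excludes 0.
    """
    out = {}
    for c, name in enumerate(COVARIATE_NAMES):
        delta = (post.beta[:, :, 1, c] - post.beta[:, :, 0, c]).ravel()
        med, lo, hi = _median_ci(delta)
        out[name] = {
            "median": med,
            "ci_lo": lo,
            "ci_hi": hi,
            "credible": bool(lo > 0 or hi < 0),
        }
    return pd.DataFrame(out).T


def _posterior_median_weights(post: Posterior) -> tuple[np.ndarray, np.ndarray]:
    """Cell-wise posterior median weights, renormalized onto the simplex."""
    out = []
    for w in (post.w_asw, post.w_vpd):
        med = np.median(w.reshape(-1, 5, 5), axis=0)
        out.append(med / med.sum())
    return tuple(out)


def effect_sizes(post: Posterior, design: ModelDesign) -> pd.DataFrame:
    """Posterior effect sizes: response change per 1 SD of each covariate.

    BA and sqrt-dbh enter standardized, so their realized SD is 1 and the
    effect equals the coefficient.  For antecedent terms and interactions
    the SD is that of the realized column at the posterior-median weights
    (the weighted index does not have unit SD even though the cube cells
    are standardized).
    """
    if not design.standardizer.sds:
        raise ValueError("design carries no stored standardization SDs")
    w_a, w_v = _posterior_median_weights(post)
    idx_a = antecedent_index(w_a, design.cube_asw)
    idx_v = antecedent_index(w_v, design.cube_vpd)
    cols = {
        "BA": design.ba,
        "sqrt_dbh": design.sqrt_dbh,
        "ASW": idx_a,
        "VPD": idx_v,
        "ASWxdbh": idx_a * design.sqrt_dbh,
        "VPDxdbh": idx_v * design.sqrt_dbh,
        "ASWxVPD": idx_a * idx_v,
    }
    rows = {}
    for s, slab in enumerate(STATUS_LABELS):
        for c, cname in enumerate(COVARIATE_NAMES):
            sd = float(np.std(cols[cname]))
            eff = post.beta[:, :, s, c].ravel() * sd
            med, lo, hi = _median_ci(eff)
            rows[f"{slab}_{cname}"] = {
                "covariate_sd": sd,
                "median": med,
                "ci_lo": lo,
                "ci_hi": hi,
            }
    return pd.DataFrame(rows).T


def _predictions(post: Posterior, design: ModelDesign, n_draws: int) -> tuple[np.ndarray, np.ndarray]:
    """(mu draws (D, n), sigma draws (D,)) on an evenly spaced draw subset."""
    C, K = post.phi.shape
    total = C * K
    take = min(n_draws, total)
    sel = np.linspace(0, total - 1, take).astype(int)
    beta = post.pooled(post.beta)[sel]
    phi = post.pooled(post.phi[..., None])[sel, 0]
    sigma = post.pooled(post.sigma[..., None])[sel, 0]
    a = post.pooled(post.a)[sel]
    d_block = post.pooled(post.d_block)[sel] if post.d_block.shape[2] else None
    d_tree = post.pooled(post.d_tree)[sel] if post.d_tree.shape[2] else None
    w_a = post.pooled(post.w_asw)[sel].reshape(take, 25)
    w_v = post.pooled(post.w_vpd)[sel].reshape(take, 25)

    idx_a = design.cube_asw @ w_a.T  # (n, D)
    idx_v = design.cube_vpd @ w_v.T
    dbh = design.sqrt_dbh[:, None]
    n = design.n_rows
    mu = np.zeros((take, n))
    beta_rows = beta[:, design.status, :]  # (D, n, 7)
    mu += beta_rows[:, :, 0] * design.ba
    mu += beta_rows[:, :, 1] * design.sqrt_dbh
    mu += beta_rows[:, :, 2] * idx_a.T
    mu += beta_rows[:, :, 3] * idx_v.T
    mu += beta_rows[:, :, 4] * (idx_a * dbh).T
    mu += beta_rows[:, :, 5] * (idx_v * dbh).T
    mu += beta_rows[:, :, 6] * (idx_a * idx_v).T
    mu += phi[:, None] * design.prior_y
    if a.shape[1] == 1 and a.shape[2] == 1:  # flat intercept
        mu += a[:, 0, 0][:, None]
    else:
        mu += a[:, design.site_idx, design.status]
    if d_block is not None and d_block.shape[1]:
        mu += d_block[:, design.block_idx]
    if d_tree is not None and d_tree.shape[1]:
        mu += d_tree[:, design.tree_idx]
    return mu, sigma


def bayesian_r2_rmse(
    post: Posterior, design: ModelDesign, n_draws: int = 400
) -> tuple[np.ndarray, float]:
    """Bayesian R² draws and RMSE of posterior-median predictions.

    Per draw, R² = Var(mu) / (Var(mu) + sigma²); RMSE compares the
    observed transformed response with the row-wise posterior-median
    prediction.  ``n_draws`` evenly spaced pooled draws are used.
    """
    mu, sigma = _predictions(post, design, n_draws)
    var_mu = mu.var(axis=1)
    r2 = var_mu / (var_mu + sigma**2)
    pred = np.median(mu, axis=0)
    rmse = float(np.sqrt(np.mean((design.y - pred) ** 2)))
    return r2, rmse


def median_predictions(post: Posterior, design: ModelDesign, n_draws: int = 400) -> np.ndarray:
    """Row-wise posterior-median predictions of the transformed response."""
    mu, _ = _predictions(post, design, n_draws)
    return np.median(mu, axis=0)


def yearly_weight_totals(w) -> np.ndarray:
    """Per-lag totals (summed over seasons) of a simplex weight matrix."""
    from .model import AntecedentWeights

    wm = w.w if isinstance(w, AntecedentWeights) else np.asarray(w, dtype=float)
    if wm.shape != (5, 5):
        raise ValueError("expected a 5x5 weight matrix")
    if np.any(wm < 0) or abs(wm.sum() - 1.0) > 1e-8:
        raise ValueError("weights are off the simplex")
    return wm.sum(axis=0)


@dataclass
class FitSummary:
    """Bundle of everything the model run reports."""

    params: pd.DataFrame
    differences: pd.DataFrame
    effects: pd.DataFrame
    weight_totals: pd.DataFrame
    r2_median: float
    r2_ci: tuple[float, float]
    rmse: float
    max_rhat: float
    converged: bool

    def to_text(self) -> str:
        lines = [
            "SAM growth model fit summary",
            f"  max R-hat: {self.max_rhat:.4f} ({'converged' if self.converged else 'NOT CONVERGED'})",
            f"  Bayesian R2 (median): {self.r2_median:.3f}  95% CrI [{self.r2_ci[0]:.3f}, {self.r2_ci[1]:.3f}]",
            f"  RMSE (transformed scale): {self.rmse:.3f}",
            "",
            "Parameters (median [95% CrI], R-hat):",
        ]
        for name, r in self.params.iterrows():
            lines.append(
                f"  {name:28s} {r['median']:8.3f} [{r['ci_lo']:8.3f}, {r['ci_hi']:8.3f}]  {r['rhat']:.3f}"
            )
        lines.append("")
        lines.append("Treated - untreated contrasts:")
        for name, r in self.differences.iterrows():
            star = " *" if r["credible"] else ""
            lines.append(
                f"  {name:12s} {r['median']:8.3f} [{r['ci_lo']:8.3f}, {r['ci_hi']:8.3f}]{star}"
            )
        lines.append("")
        lines.append("Per-lag weight totals (posterior medians of lag totals):")
        for name, r in self.weight_totals.iterrows():
            vals = "  ".join(f"{v:.3f}" for v in r.to_numpy())
            lines.append(f"  {name:6s} {vals}")
        return "\n".join(lines)


def fit_summary(post: Posterior, design: ModelDesign, n_r2_draws: int = 400) -> FitSummary:
    """Full report: parameter table, contrasts, effect sizes, fit statistics."""
    params = summarize_posterior(post)
    r2, rmse = bayesian_r2_rmse(post, design, n_draws=n_r2_draws)
    totals = {}
    for var, w in (("asw", post.w_asw), ("vpd", post.w_vpd)):
        lag_draws = w.sum(axis=2).reshape(-1, 5)  # per-lag totals per draw
        totals[var] = np.median(lag_draws, axis=0)
    weight_totals = pd.DataFrame(totals, index=[f"lag{l}" for l in range(5)]).T
    max_rhat = float(params["rhat"].max())
    return FitSummary(
        params=params,
        differences=pairwise_treatment_differences(post),
        effects=effect_sizes(post, design),
        weight_totals=weight_totals,
        r2_median=float(np.median(r2)),
        r2_ci=(float(np.quantile(r2, 0.025)), float(np.quantile(r2, 0.975))),
        rmse=rmse,
        max_rhat=max_rhat,
        converged=bool(max_rhat < RHAT_THRESHOLD),
    )
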