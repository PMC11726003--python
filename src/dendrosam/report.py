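"""Descriptive treatment statistics and post-fit residual diagnostics.

Descriptive statistics are computed on untransformed BAI (mm² yr⁻¹): mean
BAI by unit status and period (pre/post each block's thinning year, the
thin year itself counting as pre), the percent difference between treated
and untreated units after treatment, the average per-tree percent change
against its own pre-treatment baseline, and the share of trees that
increased or decreased.

Residual diagnostics regress the model residuals of treated rings on
time since thinning, time since burning and the percent of plot basal
area removed, to check for treatment-time structure the model did not
absorb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bai import BaiSeries, TreeMeta
from .design import ModelDesign
from .posterior import Posterior
from .summarize import median_predictions

__all__ = ["DescriptiveSummary", "descriptive_bai_summary", "ResidualDiagnostics", "residual_diagnostics"]


@dataclass
class DescriptiveSummary:
    """Treatment-descriptive BAI statistics (all on the mm² yr⁻¹ scale)."""

    mean_bai: pd.DataFrame  # index: (treated-unit/untreated-unit), columns: pre/post
    percent_difference_post: float  # treated vs untreated units, post period
    mean_percent_change: pd.Series  # per-unit-status mean of per-tree % change
    fraction_increasing: pd.Series
    fraction_decreasing: pd.Series
    n_trees: pd.Series


def descriptive_bai_summary(
    bai: Mapping[str, BaiSeries] | Sequence[BaiSeries],
    meta: Mapping[str, TreeMeta],
    thin_year_by_block: Mapping[str, int],
) -> DescriptiveSummary:
    """Pre/post treatment BAI summaries over tree-years and trees.

    Every tree uses its own block's thinning year for the period split,
    so untreated-unit trees are split at the year their paired treated
    unit was thinned.  Trees with an empty pre or post period are
    excluded with a warning.
    """
    if not isinstance(bai, Mapping):
        bai = {s.tree_id: s for s in bai}
    year_means: dict[tuple[str, str], list] = {}
    per_tree = []
    for tid, series in bai.items():
        m = meta[tid]
        thin = thin_year_by_block.get(m.block_id)
        if thin is None:
            warnings.warn(f"tree {tid}: block {m.block_id} has no thin year; skipped")
            continue
        pre_mask = series.years <= thin
        post_mask = ~pre_mask
        if not pre_mask.any() or not post_mask.any():
            warnings.warn(f"tree {tid}: empty pre or post period; excluded")
            continue
        status = m.unit_status
        year_means.setdefault((status, "pre"), []).extend(series.bai_mm2[pre_mask])
        year_means.setdefault((status, "post"), []).extend(series.bai_mm2[post_mask])
        pre_mean = float(series.bai_mm2[pre_mask].mean())
        post_mean = float(series.bai_mm2[post_mask].mean())
        change = (post_mean - pre_mean) / pre_mean * 100.0 if pre_mean > 0 else np.nan
        per_tree.append({"tree_id": tid, "status": status, "pct_change": change})
    if not per_tree:
        raise ValueError("no usable trees for descriptive summary")

    mean_bai = pd.DataFrame(
        {
            period: {
                status: float(np.mean(year_means.get((status, period), [np.nan])))
                for status in ("treated-unit", "untreated-unit")
            }
            for period in ("pre", "post")
        }
    )
    mt = mean_bai.loc["treated-unit", "post"]
    mu = mean_bai.loc["untreated-unit", "post"]
    pct_diff = (mt - mu) / mu * 100.0

    pt = pd.DataFrame(per_tree)
    grp = pt.groupby("status")["pct_change"]
    return DescriptiveSummary(
        mean_bai=mean_bai,
        percent_difference_post=float(pct_diff),
        mean_percent_change=grp.mean(),
        fraction_increasing=grp.apply(lambda x: float((x > 0).mean())),
        fraction_decreasing=grp.apply(lambda x: float((x < 0).mean())),
        n_trees=grp.size(),
    )


@dataclass
class ResidualDiagnostics:
    """Residual-vs-treatment-history trends for treated rings.

    One row per available predictor (years_since_thinning,
    years_since_burning, pct_ba_removed): least-squares slope, 95%
    confidence bounds and a flag marking intervals that exclude 0.
    """

    trends: pd.DataFrame
    residuals: pd.DataFrame = field(repr=False, default=None)


def _trend_row(x: np.ndarray, resid: np.ndarray) -> dict:
    res = stats.linregress(x, resid)
    # 95% CI from the slope's standard error, t distribution
    tcrit = stats.t.ppf(0.975, df=x.size - 2)
    lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
    return {
        "slope": res.slope,
        "ci_lo": lo,
        "ci_hi": hi,
        "excludes_zero": bool(lo > 0 or hi < 0),
        "n": int(x.size),
    }


def residual_diagnostics(
    post: Posterior,
    design: ModelDesign,
    meta: Mapping[str, TreeMeta],
    pct_ba_removed_by_plot: Mapping[str, float] | None = None,
    n_pred_draws: int = 400,
) -> ResidualDiagnostics:
    """Trends of treated-ring residuals against treatment history.

    The burn panel is produced only for trees carrying burn years; when
    no tree has any it is skipped.  ``pct_ba_removed_by_plot`` enables the
    treatment-intensity panel.
    """
    resid = design.y - median_predictions(post, design, n_draws=n_pred_draws)
    treated = design.status == 1
    if not treated.any():
        raise ValueError("no treated rings in the design")
    rows = []
    tst, tsb, pctrem, keep_burn = [], [], [], []
    for i in np.nonzero(treated)[0]:
        tid = design.tree_labels[design.tree_idx[i]]
        m = meta[tid]
        year = int(design.years[i])
        tst.append(year - int(m.thin_year))
        burns = [b for b in m.burn_years if b <= year]
        if burns:
            tsb.append(year - max(burns))
            keep_burn.append(len(rows))
        else:
            tsb.append(np.nan)
        pctrem.append(
            pct_ba_removed_by_plot.get(m.plot_id, np.nan) if pct_ba_removed_by_plot else np.nan
        )
        rows.append({"tree_id": tid, "year": year, "residual": float(resid[i])})
    df = pd.DataFrame(rows)
    df["years_since_thinning"] = tst
    df["years_since_burning"] = tsb
    df["pct_ba_removed"] = pctrem

    trends = {}
    r = df["residual"].to_numpy()
    trends["years_since_thinning"] = _trend_row(df["years_since_thinning"].to_numpy(float), r)
    burn_ok = df["years_since_burning"].notna()
    if burn_ok.any():
        trends["years_since_burning"] = _trend_row(
            df.loc[burn_ok, "years_since_burning"].to_numpy(float), r[burn_ok.to_numpy()]
        )
    rem_ok = df["pct_ba_removed"].notna()
    if rem_ok.any() and df.loc[rem_ok, "pct_ba_removed"].nunique() > 1:
        trends["pct_ba_removed"] = _trend_row(
            df.loc[rem_ok, "pct_ba_removed"].to_numpy(float), r[rem_ok.to_numpy()]
        )
    return ResidualDiagnostics(trends=pd.DataFrame(trends).T, residuals=df)
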