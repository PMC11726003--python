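"""Descriptive treatment statistics and residual diagnostics."""

import numpy as np
import pytest

from dendrosam import BaiSeries, TreeMeta, descriptive_bai_summary, residual_diagnostics
from dendrosam.report import DescriptiveSummary
from conftest import make_posterior


def tree(tid, unit, pre, post, thin=2000, years=(1990, 2010), block="B1"):
    yrs = np.arange(years[0], years[1] + 1)
    vals = np.where(yrs <= thin, pre, post).astype(float)
    meta = TreeMeta(
        tid, f"{block}{unit}P1", block, "S1",
        "treated-unit" if unit == "T" else "untreated-unit",
        30.0, thin_year=thin if unit == "T" else None,
    )
    return BaiSeries(tid, yrs, vals), meta


class TestDescriptiveSummary:
    def test_no_change_gives_zero_difference(self):
        series, metas = {}, {}
        for tid, unit in [("t1", "T"), ("t2", "T"), ("u1", "U"), ("u2", "U")]:
            s, m = tree(tid, unit, 100.0, 100.0)
            series[tid], metas[tid] = s, m
        d = descriptive_bai_summary(series, metas, {"B1": 2000})
        assert d.percent_difference_post == pytest.approx(0.0)
        assert (d.mean_percent_change == 0).all()
        assert (d.fraction_increasing == 0).all()
        assert (d.fraction_decreasing == 0).all()

    def test_hand_arithmetic_toy_table(self):
        # treated: pre 100 -> post 150 (+50%); untreated: 100 -> 80 (-20%)
        series, metas = {}, {}
        s, m = tree("t1", "T", 100.0, 150.0)
        series["t1"], metas["t1"] = s, m
        s, m = tree("u1", "U", 100.0, 80.0)
        series["u1"], metas["u1"] = s, m
        d = descriptive_bai_summary(series, metas, {"B1": 2000})
        assert d.mean_percent_change["treated-unit"] == pytest.approx(50.0)
        assert d.mean_percent_change["untreated-unit"] == pytest.approx(-20.0)
        assert d.percent_difference_post == pytest.approx((150 - 80) / 80 * 100)
        assert d.fraction_increasing["treated-unit"] == 1.0
        assert d.fraction_decreasing["untreated-unit"] == 1.0

    def test_tree_with_empty_period_excluded(self):
        series, metas = {}, {}
        s, m = tree("t1", "T", 100.0, 150.0)
        series["t1"], metas["t1"] = s, m
        s2, m2 = tree("t2", "T", 100.0, 150.0, years=(2005, 2010))  # no pre period
        series["t2"], metas["t2"] = s2, m2
        s3, m3 = tree("u1", "U", 100.0, 90.0)
        series["u1"], metas["u1"] = s3, m3
        with pytest.warns(UserWarning, match="empty pre or post"):
            d = descriptive_bai_summary(series, metas, {"B1": 2000})
        assert d.n_trees["treated-unit"] == 1

    def test_known_multiplier_recovered(self):
        """Noisy BAI with a known treated-unit multiplier m: the post-period
        percent difference lands near (m - 1) * 100."""
        rng = np.random.default_rng(0)
        m_true = 2.0
        series, metas = {}, {}
        for i in range(20):
            yrs = np.arange(1985, 2019)
            base = rng.uniform(800, 1200)
            noise = rng.normal(1.0, 0.1, yrs.size)
            treated = i < 10
            mult = np.where(yrs > 2000, m_true if treated else 1.0, 1.0)
            vals = base * mult * noise
            tid = f"x{i}"
            series[tid] = BaiSeries(tid, yrs, vals)
            metas[tid] = TreeMeta(
                tid, "P1", "B1", "S1",
                "treated-unit" if treated else "untreated-unit",
                30.0, thin_year=2000 if treated else None,
            )
        d = descriptive_bai_summary(series, metas, {"B1": 2000})
        assert d.percent_difference_post == pytest.approx(100.0, abs=25.0)
        assert d.fraction_increasing["treated-unit"] == 1.0


def _design_with_truth_posterior(seed=1):
    from dendrosam import SimConfig, generate_dataset
    from dendrosam.simulate import default_true_parameters

    tp = default_true_parameters(2)
    tp["sigma"] = 0.0
    tp["tau_block"] = 0.0
    tp["tau_tree"] = 0.0
    cfg = SimConfig(seed=seed, true_params=tp)
    design, truth = generate_dataset(cfg)
    p = truth.params
    post = make_posterior(
        beta=p.coef.beta, phi=p.coef.phi, sigma=1e-8, a=p.intercepts.a,
        w_asw=p.w_asw.w, w_vpd=p.w_vpd.w,
        d_block=p.intercepts.d_block, d_tree=p.intercepts.d_tree,
    )
    meta = {}
    for i, tid in enumerate(design.tree_labels):
        rows = design.tree_idx == i
        treated_any = np.any(design.status[rows] == 1)
        block = design.block_labels[design.block_idx[rows][0]]
        thin = int(cfg.thin_years[design.block_idx[rows][0] % len(cfg.thin_years)])
        meta[tid] = TreeMeta(
            tid, f"{block}P", block, design.site_labels[design.site_idx[rows][0]],
            "treated-unit" if treated_any else "untreated-unit",
            30.0,
            thin_year=thin if treated_any else None,
            burn_years=(thin + 2,) if treated_any else (),
        )
    return design, post, meta, cfg


class TestResidualDiagnostics:
    def test_zero_residuals_give_zero_slopes(self):
        design, post, meta, _ = _design_with_truth_posterior()
        diag = residual_diagnostics(post, design, meta)
        assert abs(diag.trends.loc["years_since_thinning", "slope"]) < 1e-6
        assert not diag.trends.loc["years_since_thinning", "excludes_zero"]

    def test_injected_thinning_trend_recovered(self):
        design, post, meta, _ = _design_with_truth_posterior()
        slope_true = 0.01
        treated = design.status == 1
        thin_of_block = {}
        for tid, m in meta.items():
            if m.thin_year:
                thin_of_block[m.block_id] = m.thin_year
        tst = np.zeros(design.n_rows)
        labels = np.asarray(design.block_labels)[design.block_idx]
        for bl, thin in thin_of_block.items():
            rows = (labels == bl) & treated
            tst[rows] = design.years[rows] - thin
        design.y = design.y + slope_true * tst
        diag = residual_diagnostics(post, design, meta)
        assert diag.trends.loc["years_since_thinning", "slope"] == pytest.approx(
            slope_true, abs=0.005
        )
        assert diag.trends.loc["years_since_thinning", "excludes_zero"]

    def test_burn_panel_skipped_without_burn_years(self):
        design, post, meta, _ = _design_with_truth_posterior()
        meta = {
            k: TreeMeta(m.tree_id, m.plot_id, m.block_id, m.site_id, m.unit_status,
                        m.dbh_2019_cm, m.thin_year, ())
            for k, m in meta.items()
        }
        diag = residual_diagnostics(post, design, meta)
        assert "years_since_burning" not in diag.trends.index
        assert "years_since_thinning" in diag.trends.index

    def test_no_treated_rings_rejected(self):
        design, post, meta, _ = _design_with_truth_posterior()
        design.status = np.zeros_like(design.status)
        with pytest.raises(ValueError, match="treated"):
            residual_diagnostics(post, design, meta)
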