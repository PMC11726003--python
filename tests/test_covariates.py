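"""Covariate construction: interpolation, dbh, VPD, seasons, standardization."""

import numpy as np
import pandas as pd
import pytest

from dendrosam import (
    DailyClimateSeries,
    PlotSurveyTable,
    RingWidthSeries,
    Standardizer,
    daily_vpd,
    plot_basal_area_annual,
    reconstruct_dbh_series,
    seasonal_lag_matrix,
    seasonal_table_to_lag_matrix,
    treatment_status,
)
from dendrosam.covariates import SEASON_ORDER, saturation_vapor_pressure


class TestBasalAreaInterpolation:
    def test_midpoint_and_extrapolation(self):
        tbl = PlotSurveyTable("p", np.array([2000, 2010]), np.array([30.0, 20.0]))
        out = plot_basal_area_annual(tbl, [1995, 2005, 2015])
        np.testing.assert_allclose(out, [30.0, 25.0, 20.0])

    def test_three_survey_piecewise(self):
        tbl = PlotSurveyTable("p", np.array([2000, 2004, 2010]), np.array([30.0, 22.0, 28.0]))
        assert plot_basal_area_annual(tbl, [2007])[0] == pytest.approx(22 + 3 * 6 / 6)

    def test_bounded_by_survey_range(self):
        tbl = PlotSurveyTable("p", np.array([2000, 2003, 2010]), np.array([31.0, 18.0, 25.0]))
        out = plot_basal_area_annual(tbl, np.arange(1990, 2020))
        assert out.min() >= 18.0 and out.max() <= 31.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PlotSurveyTable("p", np.array([], dtype=int), np.array([]))


class TestDbhReconstruction:
    def test_cumulative_subtraction(self):
        # 5 mm rings in 2017 and 2018; anchor dbh 40 cm in 2019
        ring = RingWidthSeries("t", np.array([2016, 2017, 2018]), np.array([5.0, 5.0, 5.0]))
        dbh = reconstruct_dbh_series(40.0, ring)
        assert dbh.loc[2018] == pytest.approx(40.0)  # no 2019 ring measured
        assert dbh.loc[2017] == pytest.approx(39.0)
        assert dbh.loc[2016] == pytest.approx(38.0)

    def test_zero_width_year_changes_nothing(self):
        r1 = RingWidthSeries("t", np.array([2017, 2018]), np.array([0.0, 3.0]))
        dbh = reconstruct_dbh_series(40.0, r1)
        assert dbh.loc[2017] == pytest.approx(dbh.loc[2018] - 0.6)
        assert dbh.loc[2017] == pytest.approx(40.0 - 0.6)

    def test_non_increasing_backwards(self):
        rng = np.random.default_rng(0)
        ring = RingWidthSeries("t", np.arange(1980, 2019), rng.uniform(0, 3, 39))
        dbh = reconstruct_dbh_series(60.0, ring)
        assert np.all(np.diff(dbh.to_numpy()) >= 0)

    def test_impossible_reconstruction_rejected(self):
        ring = RingWidthSeries("t", np.array([2016, 2017, 2018]), np.array([100.0, 100.0, 100.0]))
        with pytest.raises(ValueError, match="<= 0"):
            reconstruct_dbh_series(30.0, ring)


class TestDailyVpd:
    def test_saturation_gives_zero(self):
        es = saturation_vapor_pressure(20.0)
        assert daily_vpd(20.0, es) == pytest.approx(0.0, abs=1e-12)

    def test_magnus_closed_form(self):
        assert saturation_vapor_pressure(20.0) == pytest.approx(2.339, abs=2e-3)
        assert daily_vpd(20.0, 1.169) == pytest.approx(1.170, abs=2e-3)

    def test_supersaturation_clamped(self):
        assert daily_vpd(10.0, 5.0) == 0.0

    def test_range_checks(self):
        with pytest.raises(ValueError):
            daily_vpd(60.0, 1.0)
        with pytest.raises(ValueError):
            daily_vpd(10.0, -0.5)


def _daily(unit, start, end, fn):
    dates = pd.date_range(start, end, freq="D")
    return DailyClimateSeries(unit, dates, np.array([fn(d) for d in dates], dtype=float))


class TestSeasonalLagMatrix:
    def test_constant_series(self):
        s = _daily("p", "1994-12-01", "2000-11-30", lambda d: 7.5)
        m = seasonal_lag_matrix(s, 2000)
        np.testing.assert_allclose(m, 7.5)

    def test_day_count_oracle_for_winter(self):
        # value = calendar year; winter lag-0 of 2000 mixes Dec 1999 and Jan-Feb 2000
        s = _daily("p", "1994-12-01", "2000-11-30", lambda d: float(d.year))
        m = seasonal_lag_matrix(s, 2000)
        expected = (31 * 1999 + 60 * 2000) / 91  # 2000 is a leap year: 31+29 days
        assert m[0, 0] == pytest.approx(expected)

    def test_lag4_spring_is_mar_apr_1996(self):
        s = _daily("p", "1994-12-01", "2000-11-30", lambda d: float(d.year))
        m = seasonal_lag_matrix(s, 2000)
        assert m[SEASON_ORDER.index("spring"), 4] == pytest.approx(1996.0)

    def test_missing_days_reported(self):
        dates = pd.date_range("1994-12-01", "2000-11-30", freq="D")
        keep = dates != pd.Timestamp("1998-07-15")
        s = DailyClimateSeries("p", dates[keep], np.ones(int(keep.sum())))
        with pytest.raises(ValueError, match="1998-07-15"):
            seasonal_lag_matrix(s, 2000)

    def test_permutation_stable(self):
        rng = np.random.default_rng(5)
        dates = pd.date_range("1994-12-01", "2000-11-30", freq="D")
        vals = rng.uniform(0, 10, len(dates))
        perm = rng.permutation(len(dates))
        m1 = seasonal_lag_matrix(DailyClimateSeries("p", dates, vals), 2000)
        m2 = seasonal_lag_matrix(DailyClimateSeries("p", dates[perm], vals[perm]), 2000)
        np.testing.assert_allclose(m1, m2)

    def test_seasonal_table_matches_daily_for_constant(self):
        tbl = {(s, y): 3.0 for s in SEASON_ORDER for y in range(1995, 2001)}
        np.testing.assert_allclose(seasonal_table_to_lag_matrix(tbl, 2000), 3.0)


class TestTreatmentStatus:
    @pytest.mark.parametrize(
        "ring,thin,expected",
        [
            (2005, None, "untreated"),
            (1999, 2000, "untreated"),
            (2000, 2000, "untreated"),  # thin-year rings stay untreated
            (2001, 2000, "treated"),
        ],
    )
    def test_rule(self, ring, thin, expected):
        assert treatment_status(ring, thin) == expected


class TestStandardizer:
    def test_population_sd_convention(self):
        std = Standardizer()
        z = std.fit_transform("x", np.array([0.0, 2.0]))
        np.testing.assert_allclose(z, [-1.0, 1.0])
        assert std.means["x"] == 1.0 and std.sds["x"] == 1.0

    def test_roundtrip(self):
        std = Standardizer()
        x = np.random.default_rng(0).normal(5, 3, 100)
        z = std.fit_transform("x", x)
        np.testing.assert_allclose(std.inverse("x", z), x, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero SD"):
            Standardizer().fit_transform("c", np.full(10, 3.0))
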