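"""Regression covariates for the growth model.

Covariates per tree-year:

* plot basal area (m²/ha), annualized from episodic surveys by linear
  interpolation with constant extrapolation;
* tree size, reconstructed backwards from the 2019 dbh and cumulative
  ring widths, square-root transformed, taken from the year *before* the
  growth ring;
* seasonal lag matrices (5 seasons × lag years 0–4) of available soil
  water (plot scale) and vapor pressure deficit (block scale);
* binary treatment status per ring (treated only in years after the
  unit's thinning);
* prior-year power-transformed BAI (autoregressive term).

Season definitions: winter = prior December–current February, spring =
March–April, early summer = May–June, late summer = July–September,
fall = October–November.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bai import RingWidthSeries

__all__ = [
    "SEASONS",
    "N_SEASONS",
    "N_LAGS",
    "PlotSurveyTable",
    "DailyClimateSeries",
    "plot_basal_area_annual",
    "reconstruct_dbh_series",
    "daily_vpd",
    "saturation_vapor_pressure",
    "seasonal_lag_matrix",
    "seasonal_table_to_lag_matrix",
    "treatment_status",
    "Standardizer",
]

#: season name -> months (December belongs to the *following* year's winter)
SEASONS: dict[str, tuple[int, ...]] = {
    "winter": (12, 1, 2),
    "spring": (3, 4),
    "early_summer": (5, 6),
    "late_summer": (7, 8, 9),
    "fall": (10, 11),
}
SEASON_ORDER = tuple(SEASONS)
N_SEASONS = 5
N_LAGS = 5


@dataclass(frozen=True)
class PlotSurveyTable:
    """Episodic plot basal-area surveys (m²/ha), 1–4 per plot."""

    plot_id: str
    survey_years: np.ndarray
    basal_area_m2ha: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.survey_years, dtype=int)
        ba = np.asarray(self.basal_area_m2ha, dtype=float)
        object.__setattr__(self, "survey_years", years)
        object.__setattr__(self, "basal_area_m2ha", ba)
        if years.size == 0:
            raise ValueError(f"{self.plot_id}: empty survey table")
        if years.size != ba.size:
            raise ValueError(f"{self.plot_id}: years/values length mismatch")
        if years.size > 1 and not np.all(np.diff(years) > 0):
            raise ValueError(f"{self.plot_id}: survey years must be strictly increasing")
        if not np.all(np.isfinite(ba)) or np.any(ba < 0):
            raise ValueError(f"{self.plot_id}: basal area must be finite and >= 0")


@dataclass(frozen=True)
class DailyClimateSeries:
    """Daily climate record for one spatial unit (plot for ASW, block for VPD)."""

    unit_id: str
    dates: pd.DatetimeIndex
    value: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        vals = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "value", vals)
        if len(dates) != vals.size:
            raise ValueError(f"{self.unit_id}: dates/value length mismatch")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.unit_id}: values must be finite and >= 0")


def plot_basal_area_annual(surveys: PlotSurveyTable, years: Sequence[int]) -> np.ndarray:
    """Annual basal area by linear interpolation between surveys.

    Years before the first survey take the first surveyed value; years
    after the last take the last (constant extrapolation) — np.interp's
    clamping implements exactly this rule.
    """
    years = np.asarray(years, dtype=float)
    return np.interp(years, surveys.survey_years.astype(float), surveys.basal_area_m2ha)


def reconstruct_dbh_series(
    dbh_2019_cm: float, ring: RingWidthSeries
) -> pd.Series:
    """dbh (cm) at the end of each ring year, reconstructed backwards.

    dbh at the end of year *t* = 2019 dbh minus twice the summed ring
    widths of all later measured years (mm → cm).  Bark is treated as a
    constant offset carried inside the 2019 field measurement.  The
    returned series is indexed by year and covers the ring years; entry
    for the last ring year (normally 2018) equals the 2019 dbh since no
    2019 ring is measured.
    """
    if not (dbh_2019_cm > 0):
        raise ValueError("dbh_2019_cm must be > 0")
    w_cm = ring.widths_mm / 10.0
    # widths of years strictly after t, summed: suffix sum excluding year t
    suffix = np.concatenate([np.cumsum(w_cm[::-1])[::-1][1:], [0.0]])
    dbh = dbh_2019_cm - 2.0 * suffix
    if np.any(dbh <= 0):
        bad = int(ring.years[np.nonzero(dbh <= 0)[0][0]])
        raise ValueError(f"{ring.tree_id}: reconstructed dbh <= 0 at year {bad}")
    return pd.Series(dbh, index=ring.years, name="dbh_cm")


def saturation_vapor_pressure(tmean_C) -> np.ndarray:
    """Magnus-form saturation vapor pressure (kPa) over water."""
    t = np.asarray(tmean_C, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def daily_vpd(tmean_C, ea_kPa) -> np.ndarray:
    """Daily vapor pressure deficit: ``max(es(T) - ea, 0)`` in kPa."""
    t = np.asarray(tmean_C, dtype=float)
    ea = np.asarray(ea_kPa, dtype=float)
    if np.any((t <= -40) | (t >= 50)):
        raise ValueError("tmean_C outside plausible range (-40, 50)")
    if np.any(ea < 0):
        raise ValueError("ea_kPa must be >= 0")
    out = np.clip(saturation_vapor_pressure(t) - ea, 0.0, None)
    return out if out.ndim else float(out)


def _season_year_labels(dates: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
    """Assign each day a (season index, season-year); December rolls forward."""
    month = dates.month.to_numpy()
    year = dates.year.to_numpy()
    season = np.empty(len(dates), dtype=int)
    for si, months in enumerate(SEASONS.values()):
        season[np.isin(month, months)] = si
    season_year = np.where(month == 12, year + 1, year)
    return season, season_year


def seasonal_lag_matrix(series: DailyClimateSeries, ring_year: int) -> np.ndarray:
    """5×5 matrix of seasonal means (rows: seasons, cols: lags 0–4).

    Cell (s, ℓ) is the mean of daily values in season *s* of calendar year
    ``ring_year − ℓ``; the winter of year *y* spans December of *y−1*
    through February of *y* (leap days included).  Every needed day from
    December of ``ring_year − 5`` through November of ``ring_year`` must
    be present exactly once.
    """
    lo = pd.Timestamp(ring_year - 5, 12, 1)
    hi = pd.Timestamp(ring_year, 11, 30)
    mask = (series.dates >= lo) & (series.dates <= hi)
    dates = series.dates[mask]
    vals = series.value[np.asarray(mask)]
    expected = pd.date_range(lo, hi, freq="D")
    if not dates.sort_values().equals(expected):
        missing = expected.difference(dates)
        head = ", ".join(str(d.date()) for d in missing[:3])
        raise ValueError(
            f"{series.unit_id}: {len(missing)} missing day(s) in window "
            f"{lo.date()}..{hi.date()} (first: {head})"
        )
    season, season_year = _season_year_labels(dates)
    out = np.full((N_SEASONS, N_LAGS), np.nan)
    for lag in range(N_LAGS):
        yr = ring_year - lag
        in_year = season_year == yr
        for si in range(N_SEASONS):
            sel = in_year & (season == si)
            out[si, lag] = vals[sel].mean()
    return out


def seasonal_table_to_lag_matrix(
    seasonal: Mapping[tuple[str, int], float] | pd.DataFrame, ring_year: int
) -> np.ndarray:
    """Build the 5×5 lag matrix from pre-computed seasonal means.

    ``seasonal`` maps (season name, calendar year) to the seasonal mean,
    or is a DataFrame with columns season, year, value.
    """
    if isinstance(seasonal, pd.DataFrame):
        seasonal = {
            (str(r.season), int(r.year)): float(r.value) for r in seasonal.itertuples()
        }
    out = np.full((N_SEASONS, N_LAGS), np.nan)
    for lag in range(N_LAGS):
        for si, name in enumerate(SEASON_ORDER):
            key = (name, ring_year - lag)
            if key not in seasonal:
                raise ValueError(f"missing seasonal value for {key}")
            out[si, lag] = seasonal[key]
    return out


def treatment_status(ring_year: int, thin_year: int | None) -> str:
    """Ring status: treated only for years strictly after the thinning year.

    Growth in the thinning year itself is partly pre-treatment, so it
    stays untreated; trees without a thinning (untreated units) are
    untreated in every year.
    """
    if thin_year is None:
        return "untreated"
    return "treated" if ring_year > thin_year else "untreated"


@dataclass
class Standardizer:
    """Center/scale columns with stored statistics (population SD, ÷n).

    Seasonal climate cubes are standardized with a single pooled mean/SD
    per climate variable across all 25 cells, so that the relative
    seasonal contrasts the antecedent weights must apportion are
    preserved.
    """

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def fit_transform(self, name: str, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"column {name!r} contains non-finite values")
        mu = float(x.mean())
        sd = float(x.std())  # population convention (ddof=0)
        if sd == 0:
            raise ValueError(f"column {name!r} has zero SD; cannot standardize")
        self.means[name] = mu
        self.sds[name] = sd
        return (x - mu) / sd

    def transform(self, name: str, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sds[name] + self.means[name]
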