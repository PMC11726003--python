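"""Assembly of the regression table (``ModelDesign``) for the growth model.

One row per tree-year: power-transformed BAI response, standardized
covariates (plot basal area, sqrt dbh of the prior year, the two 5×5
seasonal-lag climate cubes), per-ring treatment status, nesting indices
(site / block / tree) and the prior-year transformed response for the
autoregressive term.  The first year of every tree is dropped because it
has no prior-year response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bai import TreeMeta
from .covariates import N_LAGS, N_SEASONS, SEASON_ORDER, Standardizer, treatment_status

__all__ = ["CovariateRow", "ModelDesign", "assemble_design"]

COVARIATE_NAMES = ("BA", "sqrt_dbh", "ASW", "VPD", "ASWxdbh", "VPDxdbh", "ASWxVPD")
STATUS_LABELS = ("untreated", "treated")


@dataclass(frozen=True)
class CovariateRow:
    """A single assembled tree-year row (mainly for inspection/tests)."""

    tree_id: str
    year: int
    ba: float
    sqrt_dbh: float
    cube_asw: np.ndarray  # 5x5, standardized
    cube_vpd: np.ndarray
    status: str  # "treated" | "untreated"
    prior_transformed_bai: float


@dataclass
class ModelDesign:
    """Vectorized regression table plus stored standardization statistics.

    ``cube_asw`` / ``cube_vpd`` are (n, 25) with cells flattened row-major
    as (season, lag); ``status`` is 0 untreated / 1 treated.
    """

    y: np.ndarray
    prior_y: np.ndarray
    ba: np.ndarray
    sqrt_dbh: np.ndarray
    cube_asw: np.ndarray
    cube_vpd: np.ndarray
    status: np.ndarray
    site_idx: np.ndarray
    block_idx: np.ndarray
    tree_idx: np.ndarray
    years: np.ndarray
    site_labels: tuple[str, ...]
    block_labels: tuple[str, ...]
    tree_labels: tuple[str, ...]
    standardizer: Standardizer = field(default_factory=Standardizer)

    def __post_init__(self) -> None:
        n = self.y.size
        for name in ("prior_y", "ba", "sqrt_dbh", "status", "site_idx", "block_idx", "tree_idx", "years"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"design column {name!r} length mismatch")
        for name in ("cube_asw", "cube_vpd"):
            if getattr(self, name).shape != (n, N_SEASONS * N_LAGS):
                raise ValueError(f"{name} must have shape (n, 25)")

    @property
    def n_rows(self) -> int:
        return self.y.size

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def n_blocks(self) -> int:
        return len(self.block_labels)

    @property
    def n_trees(self) -> int:
        return len(self.tree_labels)

    def row(self, i: int) -> CovariateRow:
        return CovariateRow(
            tree_id=self.tree_labels[self.tree_idx[i]],
            year=int(self.years[i]),
            ba=float(self.ba[i]),
            sqrt_dbh=float(self.sqrt_dbh[i]),
            cube_asw=self.cube_asw[i].reshape(N_SEASONS, N_LAGS),
            cube_vpd=self.cube_vpd[i].reshape(N_SEASONS, N_LAGS),
            status=STATUS_LABELS[int(self.status[i])],
            prior_transformed_bai=float(self.prior_y[i]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "tree_id": np.asarray(self.tree_labels)[self.tree_idx],
                "year": self.years,
                "y": self.y,
                "prior_y": self.prior_y,
                "ba": self.ba,
                "sqrt_dbh": self.sqrt_dbh,
                "status": np.asarray(STATUS_LABELS)[self.status],
                "site": np.asarray(self.site_labels)[self.site_idx],
                "block": np.asarray(self.block_labels)[self.block_idx],
            }
        )
        for var, cube in (("asw", self.cube_asw), ("vpd", self.cube_vpd)):
            for si, season in enumerate(SEASON_ORDER):
                for lag in range(N_LAGS):
                    df[f"{var}_{season}_lag{lag}"] = cube[:, si * N_LAGS + lag]
        return df


def assemble_design(
    transformed_bai: Mapping[str, pd.Series],
    meta: Mapping[str, TreeMeta],
    ba_annual: Mapping[str, pd.Series],
    asw_cubes: Mapping[tuple[str, int], np.ndarray],
    vpd_cubes: Mapping[tuple[str, int], np.ndarray],
    dbh_by_year: Mapping[str, pd.Series],
    year_range: tuple[int, int] = (1985, 2018),
) -> ModelDesign:
    """Assemble the regression table from per-component inputs.

    Parameters
    ----------
    transformed_bai : mapping tree_id -> Series(year -> transformed BAI)
    meta : mapping tree_id -> TreeMeta
    ba_annual : mapping plot_id -> Series(year -> basal area, m²/ha)
    asw_cubes : mapping (plot_id, ring_year) -> 5x5 matrix (raw units)
    vpd_cubes : mapping (block_id, ring_year) -> 5x5 matrix (raw units)
    dbh_by_year : mapping tree_id -> Series(year -> dbh cm at end of year)
    year_range : inclusive calendar window for the response

    The first retained ring year is ``year_range[0] + 1`` because the
    prior-year response is required.  Covariate standardization happens
    here, after assembly, with pooled statistics for the climate cubes.
    """
    y0, y1 = year_range
    tree_ids = sorted(set(transformed_bai) & set(meta))
    dropped = sorted(set(transformed_bai) - set(meta))
    if dropped:
        warnings.warn(f"{len(dropped)} series without metadata dropped: {dropped[:5]}")
    site_labels = tuple(sorted({meta[t].site_id for t in tree_ids}))
    block_labels = tuple(sorted({meta[t].block_id for t in tree_ids}))
    site_of = {s: i for i, s in enumerate(site_labels)}
    block_of = {b: i for i, b in enumerate(block_labels)}

    rows: list[dict] = []
    kept_trees: list[str] = []
    for tid in tree_ids:
        series = transformed_bai[tid]
        m = meta[tid]
        kept_any = False
        for year in range(y0 + 1, y1 + 1):
            if year not in series.index or (year - 1) not in series.index:
                continue
            if (m.plot_id, year) not in asw_cubes or (m.block_id, year) not in vpd_cubes:
                continue
            if (year - 1) not in dbh_by_year[tid].index:
                continue
            status = treatment_status(year, m.thin_year)
            rows.append(
                {
                    "tree_id": tid,
                    "year": year,
                    "y": float(series.loc[year]),
                    "prior_y": float(series.loc[year - 1]),
                    "ba_raw": float(ba_annual[m.plot_id].loc[year]),
                    "sqrt_dbh_raw": float(np.sqrt(dbh_by_year[tid].loc[year - 1])),
                    "status": 1 if status == "treated" else 0,
                    "site": site_of[m.site_id],
                    "block": block_of[m.block_id],
                    "asw": np.asarray(asw_cubes[(m.plot_id, year)], dtype=float).ravel(),
                    "vpd": np.asarray(vpd_cubes[(m.block_id, year)], dtype=float).ravel(),
                }
            )
            kept_any = True
        if kept_any:
            kept_trees.append(tid)
        else:
            warnings.warn(f"tree {tid}: no usable rows in {y0}-{y1}; excluded")
    if not rows:
        raise ValueError("design assembly produced no rows")
    tree_labels = tuple(kept_trees)
    tree_of = {t: i for i, t in enumerate(tree_labels)}

    std = Standardizer()
    ba = std.fit_transform("ba", np.array([r["ba_raw"] for r in rows]))
    sqrt_dbh = std.fit_transform("sqrt_dbh", np.array([r["sqrt_dbh_raw"] for r in rows]))
    cube_asw = np.stack([r["asw"] for r in rows])
    cube_vpd = np.stack([r["vpd"] for r in rows])
    # pooled mean/SD per climate variable across all 25 cells
    cube_asw = std.fit_transform("asw_cube", cube_asw.ravel()).reshape(cube_asw.shape)
    cube_vpd = std.fit_transform("vpd_cube", cube_vpd.ravel()).reshape(cube_vpd.shape)

    return ModelDesign(
        y=np.array([r["y"] for r in rows]),
        prior_y=np.array([r["prior_y"] for r in rows]),
        ba=ba,
        sqrt_dbh=sqrt_dbh,
        cube_asw=cube_asw,
        cube_vpd=cube_vpd,
        status=np.array([r["status"] for r in rows], dtype=int),
        site_idx=np.array([r["site"] for r in rows], dtype=int),
        block_idx=np.array([r["block"] for r in rows], dtype=int),
        tree_idx=np.array([tree_of[r["tree_id"]] for r in rows], dtype=int),
        years=np.array([r["year"] for r in rows], dtype=int),
        site_labels=site_labels,
        block_labels=block_labels,
        tree_labels=tree_labels,
        standardizer=std,
    )
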