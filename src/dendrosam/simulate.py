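"""Synthetic datasets from the reference model, with known truth.

The generator emulates the experimental layout the model is built for:
sites containing replicated blocks, each block holding a paired treated
and untreated unit with monitoring plots and cored trees; block-specific
thinning years; seasonal climate simulated as lag-1-autocorrelated annual
series per season (soil water at plot scale, vapor pressure deficit at
block scale); plot basal area that steps down at thinning by a
configurable removal fraction (default 53.8%, the pooled removal
intensity of the experiments this package targets) and regrows linearly;
and a response drawn sequentially from the model's mean function so the
autoregressive term always sees the realized prior value.

Everything is driven by one integer seed through a spawned generator
tree, so a configuration reproduces its dataset exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .bai import PowerTransform, TreeMeta
from .covariates import N_LAGS, N_SEASONS, SEASON_ORDER
from .design import ModelDesign, assemble_design
from .model import AntecedentWeights, CoefficientSet, InterceptHierarchy, SamParameters
from .sampler import MCMCConfig, fit_mcmc
from .summarize import pairwise_treatment_differences, summarize_posterior

__all__ = [
    "ClimateConfig",
    "SimConfig",
    "SyntheticTruth",
    "default_true_parameters",
    "generate_climate",
    "generate_dataset",
    "write_dataset",
    "recovery_experiment",
    "RecoveryReport",
]


def _default_w_asw() -> np.ndarray:
    # lag-0 heavy (total 0.8), concentrated in spring/early summer
    w = np.full((5, 5), 0.2 / 20.0)
    w[:, 0] = [0.08, 0.30, 0.30, 0.08, 0.04]
    return w


def _default_w_vpd() -> np.ndarray:
    # more lagged than soil water: lag-0 total 0.55
    w = np.full((5, 5), 0.45 / 20.0)
    w[:, 0] = [0.10, 0.15, 0.15, 0.10, 0.05]
    return w


@dataclass(frozen=True)
class ClimateConfig:
    """Seasonal AR(1) climate generator settings for one variable.

    ``means``/``sds`` are per-season (winter, spring, early summer, late
    summer, fall) stationary means and SDs; ``rho`` is the lag-1 year
    autocorrelation within a season; ``unit_sd`` is the SD of static
    spatial offsets between units (plots for ASW, blocks for VPD).
    """

    means: tuple[float, ...]
    sds: tuple[float, ...]
    rho: float
    unit_sd: float


DEFAULT_ASW_CLIMATE = ClimateConfig(
    means=(40.0, 35.0, 20.0, 25.0, 30.0), sds=(12.0, 12.0, 9.0, 9.0, 10.0), rho=0.3, unit_sd=2.0
)
DEFAULT_VPD_CLIMATE = ClimateConfig(
    means=(0.4, 0.8, 1.4, 1.5, 0.8), sds=(0.35, 0.40, 0.45, 0.45, 0.40), rho=0.3, unit_sd=0.05
)


def default_true_parameters(n_sites: int = 2) -> dict:
    """Generating parameters used as the desk-scale study conditions.

    Effects are on the power-transformed BAI scale with standardized
    covariates: competition depresses growth, size raises it, soil water
    helps (less so once thinned), evaporative demand hurts (more so once
    thinned), and growth is positively autocorrelated.
    """
    beta = np.array(
        [
            # BA, sqrt_dbh, ASW, VPD, ASWxdbh, VPDxdbh, ASWxVPD
            [-0.25, 0.45, 1.30, -0.80, 0.05, -0.10, 0.15],  # untreated rings
            [-0.25, 0.45, 0.80, -1.30, 0.05, -0.10, 0.15],  # treated rings
        ]
    )
    a = np.empty((n_sites, 2))
    base = 3.3 + 0.2 * np.arange(n_sites)
    a[:, 0] = base
    a[:, 1] = base + 0.5  # direct treatment lift of baseline growth
    return {
        "beta": beta,
        "phi": 0.30,
        "sigma": 0.60,
        "a": a,
        "tau_block": 0.30,
        "tau_tree": 0.40,
        "w_asw": _default_w_asw(),
        "w_vpd": _default_w_vpd(),
    }


@dataclass(frozen=True)
class SimConfig:
    """Synthetic experiment layout and generating parameters.

    Desk-scale defaults: 2 sites × 2 blocks × (treated + untreated unit)
    × 1 plot × 5 trees over 1985–2018, i.e. 40 trees and 1,320 design
    rows after the first-year drop.  ``thin_years`` assigns a thinning
    year to each block in order (recycled if short).
    """

    n_sites: int = 2
    blocks_per_site: int = 2
    plots_per_unit: int = 1
    trees_per_plot: int = 5
    year_range: tuple[int, int] = (1985, 2018)
    thin_years: tuple[int, ...] = (1999, 2001, 2003, 2005)
    removal_fraction: float = 0.538
    ba_start_range: tuple[float, float] = (25.0, 35.0)
    ba_drift: float = 0.15  # m2/ha per year, untreated accumulation
    ba_regrow: float = 0.30  # m2/ha per year after thinning
    dbh_start_range: tuple[float, float] = (20.0, 45.0)
    dbh_growth: float = 0.25  # cm per year
    asw_climate: ClimateConfig = DEFAULT_ASW_CLIMATE
    vpd_climate: ClimateConfig = DEFAULT_VPD_CLIMATE
    true_params: dict | None = None
    transform_exponent: float = 0.24
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.blocks_per_site, self.plots_per_unit, self.trees_per_plot) < 1:
            raise ValueError("all design counts must be >= 1")
        y0, y1 = self.year_range
        if y1 <= y0:
            raise ValueError("year_range must be increasing")
        for t in self.thin_years:
            if not (y0 <= t <= y1):
                raise ValueError(f"thin year {t} outside year range")
        if not (0 <= self.removal_fraction < 1):
            raise ValueError("removal_fraction must be in [0, 1)")

    def resolved_truth(self) -> dict:
        truth = default_true_parameters(self.n_sites)
        if self.true_params:
            truth.update(self.true_params)
        w = np.asarray(truth["w_asw"])
        for key in ("w_asw", "w_vpd"):
            w = np.asarray(truth[key], dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
                raise ValueError(f"true {key} must lie on the simplex")
        return truth


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters plus realized random effects for one dataset."""

    params: SamParameters
    transform: PowerTransform
    config: SimConfig

    def to_json(self, path: str | Path) -> None:
        p = self.params
        payload = {
            "beta": p.coef.beta.tolist(),
            "phi": p.coef.phi,
            "sigma": p.coef.sigma,
            "a": p.intercepts.a.tolist(),
            "d_block": p.intercepts.d_block.tolist(),
            "d_tree": p.intercepts.d_tree.tolist(),
            "tau_block": p.intercepts.tau_block,
            "tau_tree": p.intercepts.tau_tree,
            "w_asw": p.w_asw.w.tolist(),
            "w_vpd": p.w_vpd.w.tolist(),
            "transform_exponent": self.transform.exponent_b,
            "seed": self.config.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def params_from_json(path: str | Path) -> SamParameters:
        d = json.loads(Path(path).read_text())
        return SamParameters(
            coef=CoefficientSet(np.array(d["beta"]), d["phi"], d["sigma"]),
            intercepts=InterceptHierarchy(
                np.array(d["a"]),
                np.array(d["d_block"]),
                np.array(d["d_tree"]),
                d["tau_block"],
                d["tau_tree"],
            ),
            w_asw=AntecedentWeights("ASW", np.array(d["w_asw"])),
            w_vpd=AntecedentWeights("VPD", np.array(d["w_vpd"])),
        )


# ---------------------------------------------------------------------------
# layout helpers


def _layout(config: SimConfig):
    """Enumerate (site, block, unit, plot, tree) ids and memberships."""
    sites, blocks, plots, trees = [], [], [], []
    bi = 0
    for s in range(config.n_sites):
        site_id = f"S{s + 1}"
        sites.append(site_id)
        for b in range(config.blocks_per_site):
            block_id = f"{site_id}B{b + 1}"
            thin = config.thin_years[bi % len(config.thin_years)]
            blocks.append({"block_id": block_id, "site_id": site_id, "thin_year": thin})
            bi += 1
            for unit in ("T", "U"):
                for p in range(config.plots_per_unit):
                    plot_id = f"{block_id}{unit}P{p + 1}"
                    plots.append(
                        {
                            "plot_id": plot_id,
                            "block_id": block_id,
                            "site_id": site_id,
                            "unit": unit,
                            "thin_year": thin if unit == "T" else None,
                        }
                    )
                    for t in range(config.trees_per_plot):
                        trees.append(
                            {
                                "tree_id": f"{plot_id}T{t + 1:02d}",
                                "plot_id": plot_id,
                                "block_id": block_id,
                                "site_id": site_id,
                                "unit": unit,
                                "thin_year": thin if unit == "T" else None,
                            }
                        )
    return sites, blocks, plots, trees


def generate_climate(config: SimConfig, seed: int | None = None) -> dict:
    """Simulate seasonal climate series for every plot (ASW) and block (VPD).

    Returns ``{"asw": {plot_id: DataFrame}, "vpd": {block_id: DataFrame}}``
    with columns season/year/value covering ``year_range[0] - 5`` through
    ``year_range[1]``.  Seasonal values follow a stationary AR(1) across
    years with per-season mean and SD plus a static unit offset.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    _, blocks, plots, _ = _layout(config)
    y0, y1 = config.year_range
    years = np.arange(y0 - 5, y1 + 1)

    def simulate_unit(cc: ClimateConfig, offset: float) -> pd.DataFrame:
        rows = []
        for si, season in enumerate(SEASON_ORDER):
            mu, sd, rho = cc.means[si] + offset, cc.sds[si], cc.rho
            x = mu + sd * rng.standard_normal()
            innov_sd = sd * np.sqrt(1 - rho**2)
            for y in years:
                x = mu + rho * (x - mu) + innov_sd * rng.standard_normal()
                rows.append({"season": season, "year": int(y), "value": max(x, 0.0)})
        return pd.DataFrame(rows)

    asw = {}
    for p in plots:
        offset = config.asw_climate.unit_sd * rng.standard_normal()
        asw[p["plot_id"]] = simulate_unit(config.asw_climate, offset)
    vpd = {}
    for b in blocks:
        offset = config.vpd_climate.unit_sd * rng.standard_normal()
        vpd[b["block_id"]] = simulate_unit(config.vpd_climate, offset)
    return {"asw": asw, "vpd": vpd}


def _seasonal_frame_to_cubes(frame: pd.DataFrame, years: range) -> dict[int, np.ndarray]:
    table = {(r.season, int(r.year)): float(r.value) for r in frame.itertuples()}
    cubes = {}
    for ring_year in years:
        cube = np.empty((N_SEASONS, N_LAGS))
        for lag in range(N_LAGS):
            for si, season in enumerate(SEASON_ORDER):
                cube[si, lag] = table[(season, ring_year - lag)]
        cubes[ring_year] = cube
    return cubes


def _plot_ba_series(config: SimConfig, thin_year: int | None, ba0: float, years: np.ndarray) -> pd.Series:
    """Annual plot basal area: drift, step drop after thinning, regrowth."""
    y0 = years[0]
    ba = ba0 + config.ba_drift * (years - y0)
    if thin_year is not None:
        pre = ba0 + config.ba_drift * (thin_year - y0)
        post = years > thin_year
        ba = np.where(post, pre * (1 - config.removal_fraction) + config.ba_regrow * (years - thin_year), ba)
    if np.any(ba <= 0):
        raise ValueError("config produced non-positive basal area")
    return pd.Series(ba, index=years)


def _generate_inputs(config: SimConfig) -> dict:
    """Deterministic intermediate inputs shared by dataset and file writers."""
    rng_master = np.random.SeedSequence(config.seed)
    s_climate, s_effects, s_noise, s_layout = rng_master.spawn(4)
    rng_layout = np.random.default_rng(s_layout)

    sites, blocks, plots, trees = _layout(config)
    y0, y1 = config.year_range
    years_all = np.arange(y0, y1 + 1)

    climate = generate_climate(config, seed=int(s_climate.generate_state(1)[0] % (2**31)))

    ba_annual = {}
    asw_cubes = {}
    for p in plots:
        ba0 = rng_layout.uniform(*config.ba_start_range)
        ba_annual[p["plot_id"]] = _plot_ba_series(config, p["thin_year"], ba0, years_all)
        for year, cube in _seasonal_frame_to_cubes(
            climate["asw"][p["plot_id"]], range(y0, y1 + 1)
        ).items():
            asw_cubes[(p["plot_id"], year)] = cube
    vpd_cubes = {}
    for b in blocks:
        for year, cube in _seasonal_frame_to_cubes(
            climate["vpd"][b["block_id"]], range(y0, y1 + 1)
        ).items():
            vpd_cubes[(b["block_id"], year)] = cube

    meta = {}
    dbh_by_year = {}
    for t in trees:
        dbh0 = rng_layout.uniform(*config.dbh_start_range)
        dbh = dbh0 + config.dbh_growth * (years_all - y0)
        dbh_by_year[t["tree_id"]] = pd.Series(dbh, index=years_all)
        meta[t["tree_id"]] = TreeMeta(
            tree_id=t["tree_id"],
            plot_id=t["plot_id"],
            block_id=t["block_id"],
            site_id=t["site_id"],
            unit_status="treated-unit" if t["unit"] == "T" else "untreated-unit",
            dbh_2019_cm=float(dbh[-1] + config.dbh_growth),
            thin_year=t["thin_year"],
        )
    return {
        "sites": sites,
        "blocks": blocks,
        "plots": plots,
        "trees": trees,
        "climate": climate,
        "ba_annual": ba_annual,
        "asw_cubes": asw_cubes,
        "vpd_cubes": vpd_cubes,
        "meta": meta,
        "dbh_by_year": dbh_by_year,
        "noise_seed": s_noise,
        "effects_seed": s_effects,
    }


def generate_dataset(
    config: SimConfig,
) -> tuple[ModelDesign, SyntheticTruth]:
    """Draw one complete dataset from the reference model.

    Returns the assembled (standardized) design with the observed
    transformed response in ``design.y`` and the full generating truth.
    The response is simulated sequentially per tree so that the AR term
    uses the realized previous-year value; five spin-up years precede the
    first retained ring year.
    """
    inputs = _generate_inputs(config)
    rng_eff = np.random.default_rng(inputs["effects_seed"])
    rng_noise = np.random.default_rng(inputs["noise_seed"])
    truth_vals = config.resolved_truth()
    trees = inputs["trees"]
    meta = inputs["meta"]
    ba_annual = inputs["ba_annual"]
    asw_cubes = inputs["asw_cubes"]
    vpd_cubes = inputs["vpd_cubes"]
    dbh_by_year = inputs["dbh_by_year"]
    y0, y1 = config.year_range
    years_all = np.arange(y0, y1 + 1)

    # assemble covariates with a placeholder response, then simulate y
    placeholder = {
        t["tree_id"]: pd.Series(0.0, index=years_all) for t in trees
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = assemble_design(
            placeholder, meta, ba_annual, asw_cubes, vpd_cubes, dbh_by_year, (y0, y1)
        )

    # realized random effects
    tau_b, tau_c = truth_vals["tau_block"], truth_vals["tau_tree"]
    d_block = tau_b * rng_eff.standard_normal(design.n_blocks)
    d_tree = tau_c * rng_eff.standard_normal(design.n_trees)
    params = SamParameters(
        coef=CoefficientSet(truth_vals["beta"], truth_vals["phi"], truth_vals["sigma"]),
        intercepts=InterceptHierarchy(
            truth_vals["a"], d_block, d_tree, tau_b, tau_c
        ),
        w_asw=AntecedentWeights("ASW", truth_vals["w_asw"]),
        w_vpd=AntecedentWeights("VPD", truth_vals["w_vpd"]),
    )

    # row-level mean components that do not involve the AR term
    from .model import antecedent_index

    idx_a = antecedent_index(params.w_asw, design.cube_asw)
    idx_v = antecedent_index(params.w_vpd, design.cube_vpd)
    Xcov = np.column_stack(
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
    beta_rows = params.coef.beta[design.status]
    base = (
        params.intercepts.a[design.site_idx, design.status]
        + d_block[design.block_idx]
        + d_tree[design.tree_idx]
        + np.einsum("ij,ij->i", Xcov, beta_rows)
    )

    phi, sigma = params.coef.phi, params.coef.sigma
    y = np.empty(design.n_rows)
    prior = np.empty(design.n_rows)
    for tidx in range(design.n_trees):
        rows = np.nonzero(design.tree_idx == tidx)[0]  # ascending years by construction
        y_prev = base[rows[0]] / max(1 - phi, 1e-6)
        for _ in range(5):  # spin-up so the AR term starts near stationarity
            y_prev = base[rows[0]] + phi * y_prev + sigma * rng_noise.standard_normal()
        for i in rows:
            prior[i] = y_prev
            y_i = base[i] + phi * y_prev + sigma * rng_noise.standard_normal()
            y[i] = y_i
            y_prev = y_i
    design.y = y
    design.prior_y = prior

    truth = SyntheticTruth(
        params=params,
        transform=PowerTransform(config.transform_exponent),
        config=config,
    )
    return design, truth


def backtransform_bai(y_transformed: np.ndarray, transform: PowerTransform) -> np.ndarray:
    """BAI in mm² yr⁻¹ from the transformed response (negatives clipped to 0)."""
    return np.clip(y_transformed, 0.0, None) ** (1.0 / transform.exponent_b)


def write_dataset(config: SimConfig, outdir: str | Path) -> Path:
    """Write a generated dataset in the CSV formats the pipeline reads.

    Emits design matrix, plot surveys, seasonal climate (ASW per plot,
    VPD per block), treatments, tree metadata, the observed response
    (transformed and back-transformed) and the truth file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design, truth = generate_dataset(config)
    inputs = _generate_inputs(config)  # same seed => identical intermediates
    blocks, plots, trees = inputs["blocks"], inputs["plots"], inputs["trees"]
    y0, y1 = config.year_range

    design.to_dataframe().to_csv(outdir / "design_matrix.csv", index=False)

    bai = backtransform_bai(design.y, truth.transform)
    resp = design.to_dataframe()[["tree_id", "year"]].copy()
    resp["transformed_bai"] = design.y
    resp["bai_mm2"] = bai
    resp.to_csv(outdir / "response.csv", index=False)

    pd.concat(
        [df.assign(unit_id=pid) for pid, df in inputs["climate"]["asw"].items()]
    ).to_csv(outdir / "climate_asw_seasonal.csv", index=False)
    pd.concat(
        [df.assign(unit_id=bid) for bid, df in inputs["climate"]["vpd"].items()]
    ).to_csv(outdir / "climate_vpd_seasonal.csv", index=False)

    survey_rows = []
    for p in plots:
        series = inputs["ba_annual"][p["plot_id"]]
        survey_years = sorted({y0, *((p["thin_year"] + 1,) if p["thin_year"] else ()), y1})
        for sy in survey_years:
            survey_rows.append(
                {"plot_id": p["plot_id"], "year": sy, "ba_m2ha": float(series.loc[sy])}
            )
    pd.DataFrame(survey_rows).to_csv(outdir / "plot_surveys.csv", index=False)

    pd.DataFrame(
        [
            {
                "unit_id": b["block_id"],
                "thin_year": b["thin_year"],
                "burn_years": str(b["thin_year"] + 2),
            }
            for b in blocks
        ]
    ).to_csv(outdir / "treatments.csv", index=False)

    pd.DataFrame(
        [
            {
                "tree_id": m.tree_id,
                "plot_id": m.plot_id,
                "block_id": m.block_id,
                "site_id": m.site_id,
                "unit_status": m.unit_status,
                "dbh_2019_cm": m.dbh_2019_cm,
            }
            for m in inputs["meta"].values()
        ]
    ).to_csv(outdir / "tree_meta.csv", index=False)

    truth.to_json(outdir / "truth.json")
    return outdir


# ---------------------------------------------------------------------------
# recovery experiments


@dataclass
class RecoveryReport:
    """Replicated generate → fit → summarize results.

    ``coverage_table`` has one row per (replicate, parameter) with truth,
    posterior median, CrI bounds and coverage; ``replicates`` has one row
    per replicate with convergence and weight/contrast diagnostics.
    """

    coverage_table: pd.DataFrame
    replicates: pd.DataFrame
    errors: list[str] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return len(self.replicates)

    def coverage(self, converged_only: bool = True) -> float:
        df = self.coverage_table
        if converged_only and len(df):
            ok = set(self.replicates.loc[self.replicates.converged, "replicate"])
            df = df[df.replicate.isin(ok)]
        return float(df.covered.mean()) if len(df) else float("nan")

    def lag0_abs_error(self, variable: str) -> float:
        col = f"lag0_{variable}_abs_err"
        return float(self.replicates[col].mean()) if len(self.replicates) else float("nan")

    def detection_rate(self, covariate: str) -> float:
        col = f"detect_{covariate}"
        return float(self.replicates[col].mean()) if len(self.replicates) else float("nan")


_MONITORED = [f"beta_{s}_{c}" for s in ("untreated", "treated") for c in
              ("BA", "sqrt_dbh", "ASW", "VPD", "ASWxdbh", "VPDxdbh", "ASWxVPD")] + ["phi", "sigma"]


def recovery_experiment(
    sim_config: SimConfig,
    fit_config: MCMCConfig,
    n_replicates: int,
    progress: Callable[[int, int], None] | None = None,
) -> RecoveryReport:
    """Repeated generate → fit → summarize with known truth.

    Coverage is tallied for all fourteen status-specific coefficients
    plus phi and sigma; per-replicate rows also record the posterior
    median lag-0 weight totals (absolute error vs truth), whether the
    treated-vs-untreated contrast CrIs for ASW and VPD exclude zero, and
    the maximum R-hat.  Failed replicates are recorded and skipped.
    """
    cov_rows = []
    rep_rows = []
    errors: list[str] = []
    base = np.random.SeedSequence(sim_config.seed)
    for r in range(n_replicates):
        data_seed, fit_seed = [int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(2)]
        try:
            cfg_r = replace(sim_config, seed=data_seed)
            design, truth = generate_dataset(cfg_r)
            post = fit_mcmc(design, replace(fit_config, seed=fit_seed))
            params = summarize_posterior(post)
            truth_map = _truth_scalar_map(truth)
            for name in _MONITORED:
                row = params.loc[name]
                tv = truth_map[name]
                cov_rows.append(
                    {
                        "replicate": r,
                        "param": name,
                        "truth": tv,
                        "median": row["median"],
                        "ci_lo": row["ci_lo"],
                        "ci_hi": row["ci_hi"],
                        "covered": bool(row["ci_lo"] <= tv <= row["ci_hi"]),
                    }
                )
            diffs = pairwise_treatment_differences(post)
            lag0_asw = float(np.median(post.w_asw.sum(axis=2).reshape(-1, 5)[:, 0]))
            lag0_vpd = float(np.median(post.w_vpd.sum(axis=2).reshape(-1, 5)[:, 0]))
            max_rhat = float(params["rhat"].max())
            rep_rows.append(
                {
                    "replicate": r,
                    "max_rhat": max_rhat,
                    "converged": bool(max_rhat < 1.05),
                    "lag0_asw_abs_err": abs(lag0_asw - truth.params.w_asw.w.sum(axis=0)[0]),
                    "lag0_vpd_abs_err": abs(lag0_vpd - truth.params.w_vpd.w.sum(axis=0)[0]),
                    "lag0_asw": lag0_asw,
                    "lag0_vpd": lag0_vpd,
                    "detect_ASW": bool(diffs.loc["ASW", "credible"]),
                    "detect_VPD": bool(diffs.loc["VPD", "credible"]),
                }
            )
        except Exception as exc:  # keep going; report at the end
            errors.append(f"replicate {r}: {exc}")
        if progress is not None:
            progress(r + 1, n_replicates)
    return RecoveryReport(
        coverage_table=pd.DataFrame(cov_rows, columns=["replicate", "param", "truth", "median", "ci_lo", "ci_hi", "covered"]),
        replicates=pd.DataFrame(rep_rows, columns=["replicate", "max_rhat", "converged", "lag0_asw_abs_err", "lag0_vpd_abs_err", "lag0_asw", "lag0_vpd", "detect_ASW", "detect_VPD"]),
        errors=errors,
    )


def _truth_scalar_map(truth: SyntheticTruth) -> dict[str, float]:
    p = truth.params
    out = {}
    for s, slab in enumerate(("untreated", "treated")):
        for c, cname in enumerate(("BA", "sqrt_dbh", "ASW", "VPD", "ASWxdbh", "VPDxdbh", "ASWxVPD")):
            out[f"beta_{slab}_{cname}"] = float(p.coef.beta[s, c])
    out["phi"] = float(p.coef.phi)
    out["sigma"] = float(p.coef.sigma)
    return out
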