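"""End-to-end orchestration: prepare → fit → summarize → diagnose.

The pipeline reads the plain-CSV interchange formats (or a synthetic
configuration), assembles the regression table, runs the sampler, and
writes the design matrix, posterior draws, summaries, diagnostics and a
run log (seed + configuration hash) into an artifact directory.  Any
stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import rwl
from .bai import (
    BaiSeries,
    TreeMeta,
    apply_power_transform,
    bai_series,
    bark_free_diameter_at_core_height,
    estimate_power_exponent,
)
from .covariates import (
    PlotSurveyTable,
    plot_basal_area_annual,
    reconstruct_dbh_series,
    seasonal_table_to_lag_matrix,
)
from .design import assemble_design
from .report import descriptive_bai_summary, residual_diagnostics
from .sampler import MCMCConfig, fit_mcmc
from .simulate import SimConfig, generate_dataset
from .summarize import fit_summary

__all__ = ["PipelineError", "prepare_design", "run_pipeline", "read_tree_meta", "read_treatments"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def read_treatments(path) -> dict[str, dict]:
    """Treatments CSV: unit_id (block), thin_year, burn_years (;-separated)."""
    df = pd.read_csv(path)
    out = {}
    for r in df.itertuples():
        burns = ()
        raw = getattr(r, "burn_years", "")
        if isinstance(raw, str) and raw.strip():
            burns = tuple(int(x) for x in raw.split(";"))
        thin = None if pd.isna(r.thin_year) else int(r.thin_year)
        out[str(r.unit_id)] = {"thin_year": thin, "burn_years": burns}
    return out


def read_tree_meta(path, treatments: dict[str, dict] | None = None) -> dict[str, TreeMeta]:
    """Tree metadata CSV joined with block-level treatment years."""
    df = pd.read_csv(path)
    treatments = treatments or {}
    out = {}
    for r in df.itertuples():
        trt = treatments.get(str(r.block_id), {})
        thin = trt.get("thin_year") if r.unit_status == "treated-unit" else None
        out[str(r.tree_id)] = TreeMeta(
            tree_id=str(r.tree_id),
            plot_id=str(r.plot_id),
            block_id=str(r.block_id),
            site_id=str(r.site_id),
            unit_status=str(r.unit_status),
            dbh_2019_cm=float(r.dbh_2019_cm),
            thin_year=thin,
            burn_years=trt.get("burn_years", ()) if r.unit_status == "treated-unit" else (),
        )
    return out


def _read_seasonal_climate(path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path)
    return {str(uid): g[["season", "year", "value"]] for uid, g in df.groupby("unit_id")}


def prepare_design(paths: dict, year_range=(1985, 2018), anchor_year: int = 2018,
                   taper_a: float = 0.0, taper_b: float = 0.9):
    """Build the regression table from raw CSV inputs.

    ``paths`` keys: widths (RWL or long CSV), tree_meta, treatments,
    surveys, asw_seasonal, vpd_seasonal.  Series that do not reach
    ``anchor_year`` cannot be anchored on the 2019 diameter and are
    excluded with a warning.  Returns (design, transform, bai_by_tree,
    meta).
    """
    wpath = Path(paths["widths"])
    series = rwl.read_rwl(wpath) if wpath.suffix.lower() in (".rwl", ".txt") else rwl.read_width_table(wpath)
    treatments = read_treatments(paths["treatments"]) if "treatments" in paths else {}
    meta = read_tree_meta(paths["tree_meta"], treatments)

    from .bai import AffineTaperBarkModel

    model = AffineTaperBarkModel(taper_a, taper_b)
    bai_by_tree: dict[str, BaiSeries] = {}
    dbh_by_year = {}
    for s in series:
        if s.tree_id not in meta:
            warnings.warn(f"series {s.tree_id}: no metadata; skipped")
            continue
        if s.last_year < anchor_year:
            warnings.warn(f"series {s.tree_id}: ends {s.last_year} < {anchor_year}; excluded")
            continue
        m = meta[s.tree_id]
        diam_cm = bark_free_diameter_at_core_height(m.dbh_2019_cm, model)
        bai_by_tree[s.tree_id] = bai_series(s, diam_cm * 10.0 / 2.0)
        dbh_by_year[s.tree_id] = reconstruct_dbh_series(m.dbh_2019_cm, s)
    if not bai_by_tree:
        raise ValueError("no usable ring-width series")

    transform = estimate_power_exponent(list(bai_by_tree.values()))
    y0, y1 = year_range
    transformed = {}
    for tid, b in bai_by_tree.items():
        keep = (b.years >= y0) & (b.years <= y1)
        transformed[tid] = pd.Series(
            apply_power_transform(b.bai_mm2[keep], transform), index=b.years[keep]
        )

    surveys = pd.read_csv(paths["surveys"])
    ba_annual = {}
    for pid, g in surveys.groupby("plot_id"):
        g = g.sort_values("year")
        tbl = PlotSurveyTable(str(pid), g["year"].to_numpy(), g["ba_m2ha"].to_numpy())
        years = np.arange(y0, y1 + 1)
        ba_annual[str(pid)] = pd.Series(plot_basal_area_annual(tbl, years), index=years)

    asw = _read_seasonal_climate(paths["asw_seasonal"])
    vpd = _read_seasonal_climate(paths["vpd_seasonal"])
    asw_cubes = {}
    vpd_cubes = {}
    needed_plots = {meta[t].plot_id for t in bai_by_tree}
    needed_blocks = {meta[t].block_id for t in bai_by_tree}
    for pid in needed_plots:
        for year in range(y0 + 1, y1 + 1):
            asw_cubes[(pid, year)] = seasonal_table_to_lag_matrix(asw[pid], year)
    for bid in needed_blocks:
        for year in range(y0 + 1, y1 + 1):
            vpd_cubes[(bid, year)] = seasonal_table_to_lag_matrix(vpd[bid], year)

    design = assemble_design(
        transformed, meta, ba_annual, asw_cubes, vpd_cubes, dbh_by_year, year_range
    )
    return design, transform, bai_by_tree, meta


def run_pipeline(config: dict) -> Path:
    """Execute the full pipeline and write artifacts to ``config['outdir']``.

    ``config`` is a plain mapping (typically loaded from YAML):

    * ``outdir``: artifact directory;
    * either ``simulate`` (SimConfig fields) or ``paths`` (see
      :func:`prepare_design`);
    * ``mcmc``: MCMCConfig field overrides (chains, n_iter, n_burnin, seed).
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("prepare"):
        if "simulate" in config:
            sim = SimConfig(**config["simulate"])
            design, truth = generate_dataset(sim)
            truth.to_json(outdir / "truth.json")
            meta = None
        else:
            design, transform, bai_by_tree, meta = prepare_design(
                config["paths"], tuple(config.get("year_range", (1985, 2018)))
            )
            (outdir / "power_transform.json").write_text(
                json.dumps({"exponent_b": transform.exponent_b, "n_pairs": transform.n_pairs,
                            "slope": transform.slope})
            )
        design.to_dataframe().to_csv(outdir / "design_matrix.csv", index=False)

    with _stage("fit"):
        mcmc_kwargs = dict(config.get("mcmc", {}))
        if "priors" in mcmc_kwargs:  # prior hyperparameters as a nested mapping
            from .model import Priors

            mcmc_kwargs["priors"] = Priors(**mcmc_kwargs["priors"])
        mcmc = MCMCConfig(**mcmc_kwargs)
        post = fit_mcmc(design, mcmc)
        post.to_dataframe().to_csv(outdir / "posterior_draws.csv", index=False)

    with _stage("summarize"):
        summary = fit_summary(post, design)
        summary.params.to_csv(outdir / "summary_params.csv")
        summary.differences.to_csv(outdir / "summary_differences.csv")
        summary.effects.to_csv(outdir / "summary_effects.csv")
        summary.weight_totals.to_csv(outdir / "summary_weight_totals.csv")
        (outdir / "summary.txt").write_text(summary.to_text() + "\n")

    with _stage("diagnose"):
        if meta is not None:
            thin_by_block = {
                m.block_id: m.thin_year for m in meta.values() if m.thin_year is not None
            }
            if thin_by_block and any(design.status == 1):
                diag = residual_diagnostics(post, design, meta)
                diag.trends.to_csv(outdir / "residual_trends.csv")
                desc = descriptive_bai_summary(bai_by_tree, meta, thin_by_block)
                desc.mean_bai.to_csv(outdir / "descriptive_mean_bai.csv")

    (outdir / "run_log.json").write_text(
        json.dumps(
            {
                "seed": mcmc.seed,
                "config_hash": post.config_hash,
                "n_rows": design.n_rows,
                "n_trees": design.n_trees,
                "max_rhat": summary.max_rhat,
                "converged": summary.converged,
            },
            indent=1,
        )
    )
    return outdir
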