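"""End-to-end orchestration: simulate -> space -> geography -> diversity ->
model -> partition -> diagnose -> project.

Stages run in order within one process (each stage's outputs are written
as they complete, so a failed run keeps the artifacts of finished stages);
re-running with the same config reproduces identical files.  The CLI's
per-stage subcommands run the pipeline up to the requested stage —
everything is deterministic and desk-scale, so recomputation is the
simplest correct way to compose stages.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from climspace import io
from climspace.config import RunConfig
from climspace.diversity import beta_per_climate_cell, richness_per_climate_cell
from climspace.gam import PoissonGAM, map_residuals
from climspace.geography import (
    compute_cell_geography,
    find_fragments,
    geography_correlations,
)
from climspace.grid import GeoGrid
from climspace.space import build_climate_grid, fit_pca
from climspace.synthetic import (
    NicheParams,
    WorldParams,
    generate_species_ranges,
    generate_world,
)
from climspace.diagnostics import (
    envelope_quantile_fit,
    mem_axes,
    morans_correlogram,
    refit_with_mem,
    vif,
)

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "space",
    "geography",
    "diversity",
    "fit",
    "partition",
    "diagnose",
    "project",
]


def assemble_cell_table(
    space, geography_df: pd.DataFrame, richness: pd.Series, beta_df: pd.DataFrame
) -> pd.DataFrame:
    """Merge per-climate-cell means, geography, richness and beta parts."""
    t = space.cell_means.merge(geography_df, on="climate_cell_id")
    t = t.merge(richness.rename("richness"), left_on="climate_cell_id", right_index=True)
    t = t.merge(beta_df, on="climate_cell_id", how="left")
    return t


def run_pipeline(cfg: RunConfig, until: str = "project") -> dict:
    """Execute the pipeline up to (and including) ``until``; return artifacts.

    Writes CSV/JSON outputs plus a manifest under ``cfg.output_dir``; the
    returned dict exposes the in-memory objects (grid, spaces, cell
    tables, fitted results, ...) keyed by stage and resolution.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; stages: {STAGES}")
    last = STAGES.index(until)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.write(outdir / "config_resolved.yaml")
    art: dict = {"outdir": outdir}
    t0 = time.time()
    for stage in STAGES[: last + 1]:
        t_stage = time.time()
        try:
            _STAGE_FUNCS[stage](cfg, art)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info(
            "stage %s done in %.2fs (seed=%s)", stage, time.time() - t_stage, cfg.seed
        )
    io.write_manifest(outdir, cfg.to_dict(), extra={"elapsed_s": time.time() - t0})
    return art


# ----------------------------------------------------------------- stages
def _stage_simulate(cfg: RunConfig, art: dict) -> None:
    outdir = art["outdir"]
    if cfg.mode == "real":
        if cfg.grid_csv:
            grid = GeoGrid.from_csv(cfg.grid_csv)
        else:
            grid = io.load_variable_stack(cfg.variable_csvs)
        pam = io.load_pam(cfg.pam_csv, grid=grid) if cfg.pam_csv else None
        art["grid"], art["pam"] = grid, pam
        return
    wp = WorldParams(
        n_lat_bands=cfg.n_lat_bands,
        n_lon=cfg.n_lon,
        land_fraction=cfg.land_fraction,
        temp_gradient=cfg.temp_gradient,
        grf_length_scale=cfg.grf_length_scale,
        grf_sd=cfg.grf_sd,
        n_variables=cfg.n_variables,
        seed=cfg.seed,
    )
    grid = generate_world(wp)
    grid.to_csv(outdir / "world.csv")
    # species ranges need climate-space scores: build the coarsest space once
    pca = fit_pca(grid.climate_table(), log_vars=tuple(cfg.log_vars))
    space0 = build_climate_grid(pca.scores, n_intervals=cfg.resolutions[0])
    niche = NicheParams(
        n_species=cfg.n_species,
        breadth=(cfg.niche_breadth, cfg.niche_breadth),
        seed=cfg.seed + 1,
    )
    pam, truth = generate_species_ranges(
        grid, space0, niche, adjacency=cfg.adjacency, wrap=cfg.wrap
    )
    pam.to_csv(outdir / "pam.csv")
    truth.to_json(outdir / "truth.json")
    art["grid"], art["pam"], art["pca"] = grid, pam, pca


def _stage_space(cfg: RunConfig, art: dict) -> None:
    outdir = art["outdir"]
    grid: GeoGrid = art["grid"]
    if cfg.raw_axes:
        scores = grid.climate_table()[list(cfg.raw_axes)]
        scores = scores.rename(
            columns=dict(zip(cfg.raw_axes, ["pc1", "pc2"]))
        )
        art["pca"] = None
    else:
        pca = art.get("pca") or fit_pca(grid.climate_table(), log_vars=tuple(cfg.log_vars))
        art["pca"] = pca
        scores = pca.scores[["pc1", "pc2"]]
        io.write_json(
            {
                "variance_fraction": pca.variance_fraction,
                "loadings": {c: pca.loadings[c].to_dict() for c in ("pc1", "pc2")},
            },
            outdir / "pca_summary.json",
        )
    scores.rename_axis("cell_id").to_csv(outdir / "scores.csv")
    art["spaces"] = {}
    for r in cfg.resolutions:
        space = build_climate_grid(scores, n_intervals=r)
        art["spaces"][r] = space
        rdir = outdir / f"res{r}"
        rdir.mkdir(exist_ok=True)
        space.geo_to_climate.rename_axis("cell_id").to_csv(rdir / "membership.csv")
        space.cell_means.to_csv(rdir / "cell_means.csv", index=False)


def _stage_geography(cfg: RunConfig, art: dict) -> None:
    outdir = art["outdir"]
    art["fragments"], art["geography"] = {}, {}
    for r, space in art["spaces"].items():
        frags = find_fragments(space, art["grid"], adjacency=cfg.adjacency, wrap=cfg.wrap)
        geo = compute_cell_geography(space, art["grid"], frags)
        art["fragments"][r], art["geography"][r] = frags, geo
        rdir = outdir / f"res{r}"
        geo.to_csv(rdir / "geography.csv", index=False)
        rows = [
            {"climate_cell_id": cc, "fragment": i, "cell_id": cid}
            for cc, fl in frags.items()
            for i, f in enumerate(fl)
            for cid in f.cell_ids
        ]
        pd.DataFrame(rows).to_csv(rdir / "fragments.csv", index=False)
        geography_correlations(geo).to_csv(rdir / "geography_correlations.csv", index=False)


def _stage_diversity(cfg: RunConfig, art: dict) -> None:
    outdir = art["outdir"]
    if art.get("pam") is None:
        raise ValueError("no presence-absence data available")
    art["diversity"] = {}
    art["cell_tables"] = {}
    for r, space in art["spaces"].items():
        rich = richness_per_climate_cell(art["pam"], space)
        beta = beta_per_climate_cell(
            art["pam"],
            space,
            resample_sites=cfg.beta_resample_sites,
            n_resamples=cfg.beta_n_resamples,
            seed=cfg.seed,
        )
        table = assemble_cell_table(space, art["geography"][r], rich, beta)
        art["diversity"][r] = beta
        art["cell_tables"][r] = table
        table.to_csv(outdir / f"res{r}" / "cell_table.csv", index=False)


def _stage_fit(cfg: RunConfig, art: dict) -> None:
    outdir = art["outdir"]
    art["results"] = {}
    for r, table in art["cell_tables"].items():
        model = PoissonGAM.from_cell_table(
            table,
            log_area=cfg.log_area,
            drop_zero=cfg.drop_zero_richness,
            k=cfg.k,
        )
        res = model.fit()
        art["results"][r] = res
        rdir = outdir / f"res{r}"
        io.write_json(
            {
                "lambda": res.lam,
                "edf": res.edf_by_term,
                "deviance": res.deviance,
                "null_deviance": res.null_deviance,
                "metrics": res.goodness_of_fit(),
                "converged": res.converged,
            },
            rdir / "model_summary.json",
        )
        for term in model.term_names:
            res.partial_residuals(term).rename_axis("climate_cell_id").to_csv(
                rdir / f"partial_residuals_{term}.csv"
            )


def _stage_partition(cfg: RunConfig, art: dict) -> None:
    outdir = art["outdir"]
    art["partitions"] = {}
    for r, res in art["results"].items():
        part = res.partition()
        art["partitions"][r] = part
        part.to_series().rename_axis("component").rename("share").to_csv(
            outdir / f"res{r}" / "partition.csv"
        )


def _stage_diagnose(cfg: RunConfig, art: dict) -> None:
    outdir = art["outdir"]
    art["diagnostics"] = {}
    for r, res in art["results"].items():
        rdir = outdir / f"res{r}"
        coords = res.model.exog[["pc1", "pc2"]].to_numpy()
        cg = morans_correlogram(
            res.resid(cfg.residual_kind),
            coords,
            n_classes=cfg.n_distance_classes,
            n_permutations=cfg.n_permutations,
            seed=cfg.seed,
        )
        cg.to_frame().to_csv(rdir / "correlogram.csv", index=False)
        basis = mem_axes(coords)
        basis.to_frame().to_csv(rdir / "mem_axes.csv", index=False)
        mem_report = refit_with_mem(
            res,
            basis,
            coords=coords,
            n_classes=cfg.n_distance_classes,
            n_permutations=cfg.n_permutations,
            seed=cfg.seed,
        )
        vifs = vif(res.model.exog)
        vifs.rename_axis("predictor").to_csv(rdir / "vif.csv")
        art["diagnostics"][r] = {
            "correlogram": cg,
            "mem": mem_report,
            "vif": vifs,
        }
        io.write_json(
            {
                "selected_mem_axes": mem_report["selected_axes"],
                "first_class_p": mem_report["first_class_p"],
                "vif": vifs.to_dict(),
            },
            rdir / "diagnostics.json",
        )
    # latitude-isolation envelope at the finest resolution available
    r_env = max(art["cell_tables"])
    t = art["cell_tables"][r_env]
    fits = envelope_quantile_fit(
        t["mean_abs_lat"], t["isolation_frag_km"], taus=tuple(cfg.envelope_taus)
    )
    env = {
        str(k): (vars(v) if hasattr(v, "tau") else v) for k, v in fits.items()
    }
    env["resolution"] = r_env
    io.write_json(env, outdir / "envelope.json")
    art["envelope"] = fits


def _stage_project(cfg: RunConfig, art: dict) -> None:
    outdir = art["outdir"]
    art["residual_maps"] = {}
    for r, res in art["results"].items():
        clim, geo = map_residuals(res, art["spaces"][r], kind=cfg.residual_kind)
        art["residual_maps"][r] = (clim, geo)
        rdir = outdir / f"res{r}"
        clim.rename_axis("climate_cell_id").to_csv(rdir / "residuals_climate.csv")
        geo.rename_axis("cell_id").to_csv(rdir / "residuals_geographic.csv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "space": _stage_space,
    "geography": _stage_geography,
    "diversity": _stage_diversity,
    "fit": _stage_fit,
    "partition": _stage_partition,
    "diagnose": _stage_diagnose,
    "project": _stage_project,
}
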