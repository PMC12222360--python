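"""Orchestration of the synthetic end-to-end study.

Stages: ``simulate`` (landscape, prey survey, telemetry, with truth
recorded), ``occupancy`` (prey relative-abundance surfaces), ``homerange``
(clean telemetry to UDs and isopleths), ``rsf`` (used-available mixed
model and per-class selection maps), ``report`` (summary tables).  Every
stage writes a JSON manifest with input hashes so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import homerange as hr
from . import occupancy as occ
from . import rsf as rsfmod
from . import synth
from .config import RunConfig
from .glmm import RandomSpec
from .grid import read_ascii_grid, write_ascii_grid, write_geojson, read_geojson
from .grid import CovariateStack

log = logging.getLogger("habsel")

ENV_LAYERS = ["precipitation", "ndvi", "dist_water", "dist_settlement"]
PREY_SPECIES = {"buffalo": {"a0": 0.2, "coefficients": {"ndvi": 0.8}, "r": 0.35}}
TELEMETRY_BETA = {
    "adult female": {"precipitation": 0.6, "dist_water": -0.9, "ndvi": -0.7,
                     "dist_settlement": -0.25},
    "subadult female": {"precipitation": 0.4, "dist_water": -0.9, "ndvi": -0.7,
                        "dist_settlement": -0.25},
    "adult male": {"precipitation": 0.8, "dist_water": -0.9, "ndvi": -0.7,
                   "dist_settlement": -0.25},
    "subadult male": {"precipitation": -0.7, "dist_water": -0.9, "ndvi": -0.7,
                      "dist_settlement": -0.25},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, inputs: list[Path], outputs: list[Path],
                    config: RunConfig) -> Path:
    doc = {
        "stage": stage,
        "config": {k: v for k, v in vars(config).items()},
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path


def _load_stack(outdir: Path, names: list[str]) -> CovariateStack:
    stack = None
    for name in names:
        arr, grid = read_ascii_grid(outdir / f"{name}.asc")
        if stack is None:
            stack = CovariateStack(grid=grid)
        stack.add(name, arr)
    return stack


def stage_simulate(outdir, config: RunConfig, n_per_class: int = 2,
                   n_days: int | None = 90,
                   landscape_config: synth.LandscapeConfig | None = None) -> Path:
    """Generate the synthetic landscape, prey survey, and telemetry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lc = landscape_config or synth.LandscapeConfig(seed=config.seed)
    scape = synth.generate_landscape(lc)
    grid = scape.stack.grid

    stack = scape.stack
    stack.add("dist_water", cov.distance_to_features(
        grid, [scape.waterholes, scape.river] if scape.river else [scape.waterholes],
        config.line_spacing_m))
    stack.add("dist_settlement", cov.distance_to_features(grid, [scape.settlements]))
    stack.add("water_density", cov.kernel_density(
        grid, np.vstack([scape.waterholes, cov.discretize_line(scape.river)])
        if scape.river else scape.waterholes, radius=config.kernel_radius_m))
    stack.add("settlement_density", cov.kernel_density(
        grid, scape.settlements,
        cov.settlement_weights(scape.settlement_households, len(scape.settlements)),
        radius=config.kernel_radius_m))
    zstack = cov.standardize(stack)

    outputs = []
    for name in stack.names():
        p = outdir / f"{name}.asc"
        write_ascii_grid(p, stack[name], grid)
        outputs.append(p)
    zrec = outdir / "standardization.json"
    zrec.write_text(json.dumps(zstack.standardization))
    outputs.append(zrec)
    from shapely.geometry import Point
    write_geojson(outdir / "settlements.geojson",
                  [Point(*p) for p in scape.settlements],
                  [{"households": h} for h in scape.settlement_households])
    write_geojson(outdir / "waterholes.geojson", [Point(*p) for p in scape.waterholes])
    roads = synth.default_road_network(grid, config.site_grid_m)
    write_geojson(outdir / "roads.geojson", roads)
    if scape.river is not None:
        write_geojson(outdir / "river.geojson", [scape.river])

    truth: dict = {"seed": config.seed}
    for species, spec_t in PREY_SPECIES.items():
        pt = synth.PreyTruth(species=species, a0=spec_t["a0"],
                             coefficients=spec_t["coefficients"], r=spec_t["r"])
        lam = synth.simulate_prey_surface(zstack, pt)
        write_ascii_grid(outdir / f"lambda_truth_{species}.asc", lam, grid)
        records, sites = synth.simulate_track_survey(
            lam, grid, roads, pt, seed=config.seed + 11,
            site_size=config.site_grid_m, replicate_length=config.replicate_m)
        records.to_csv(outdir / f"survey_{species}.csv", index=False)
        sites.to_csv(outdir / f"sites_{species}.csv", index=False)
        outputs += [outdir / f"survey_{species}.csv", outdir / f"sites_{species}.csv"]
        truth[f"prey.{species}.a0"] = pt.a0
        truth[f"prey.{species}.r"] = pt.r
        for k, v in pt.coefficients.items():
            truth[f"prey.{species}.a.{k}"] = v

    # kernel scale tied to the landscape so ranges sit inside the extent
    tt = synth.TelemetryTruth(beta=TELEMETRY_BETA, kernel_sigma=grid.width / 12.0)
    fixes = synth.simulate_telemetry(zstack, tt, n_per_class, config.seed + 23,
                                     n_days=n_days)
    fixes.to_csv(outdir / "telemetry.csv", index=False)
    outputs.append(outdir / "telemetry.csv")
    for cls, betas in TELEMETRY_BETA.items():
        for k, v in betas.items():
            truth[f"telemetry.{cls}.{k}"] = v
    synth.write_truth_record(outdir / "truth.txt", truth)
    config.to_file(outdir / "config.txt")
    outputs += [outdir / "truth.txt", outdir / "config.txt"]
    return _write_manifest(outdir, "simulate", [], outputs, config)


def stage_occupancy(outdir, config: RunConfig,
                    candidates: list[str] | None = None) -> Path:
    """Fit and average prey occupancy models; write abundance surfaces."""
    outdir = Path(outdir)
    candidates = candidates or ["precipitation", "ndvi", "canopy"]
    base = _load_stack(outdir, sorted(set(candidates) | set(ENV_LAYERS) - {"class"}))
    zrec = json.loads((outdir / "standardization.json").read_text())
    zstack = cov.standardize_with_record(base, {k: tuple(v) for k, v in zrec.items()})
    outputs = []
    for species in PREY_SPECIES:
        records = pd.read_csv(outdir / f"survey_{species}.csv")
        sites = pd.read_csv(outdir / f"sites_{species}.csv")
        site_cov = pd.DataFrame({"site_id": sites["site_id"]})
        vals = zstack.extract(candidates, sites["x"].to_numpy(), sites["y"].to_numpy())
        for j, name in enumerate(candidates):
            site_cov[name] = vals[:, j]
        data = occ.build_detection_histories(records, config.replicate_m,
                                             site_covariates=site_cov)
        averaged, ranking, info = occ.model_selection(
            data, candidates, alpha=config.alpha,
            r_threshold=config.corr_threshold, delta=config.delta_aicc,
            seed=config.seed)
        log.info("occupancy %s: kept %s, screened out %s", species,
                 info["kept"], info["screened_out"])
        ranking.to_csv(outdir / f"occupancy_ranking_{species}.csv", index=False)
        pd.Series(averaged).to_csv(outdir / f"occupancy_averaged_{species}.csv")
        lam_hat = occ.predict_abundance(averaged, zstack)
        write_ascii_grid(outdir / f"lambda_hat_{species}.asc", lam_hat, zstack.grid)
        outputs += [outdir / f"occupancy_ranking_{species}.csv",
                    outdir / f"occupancy_averaged_{species}.csv",
                    outdir / f"lambda_hat_{species}.asc"]
    inputs = [outdir / f"survey_{s}.csv" for s in PREY_SPECIES]
    return _write_manifest(outdir, "occupancy", inputs, outputs, config)


def stage_homerange(outdir, config: RunConfig) -> Path:
    """Preprocess telemetry and build per-individual season UDs."""
    outdir = Path(outdir)
    fixes = pd.read_csv(outdir / "telemetry.csv")
    clean = hr.preprocess_telemetry(
        fixes, max_speed=config.max_speed_m_per_h,
        window_days=config.residency_window_days,
        residency_multiple=config.residency_multiple)
    clean.to_csv(outdir / "telemetry_clean.csv", index=False)
    arr, grid = read_ascii_grid(outdir / "precipitation.asc")
    index_rows = []
    polys, props = [], []
    min_days = min(config.min_days, 30)  # scaled-down runs carry < 60 days
    for ind, grp in clean.groupby("individual"):
        year = grp["timestamp"].iloc[0].year
        season = f"{year}-dry"
        cls = hr.assign_class(grp["birth_date"].iloc[0], grp["sex"].iloc[0],
                              f"{year}-{config.season_start}")
        try:
            ud = hr.build_ud(grp, grid, ind, season, cls,
                             level=config.isopleth_level, min_days=min_days)
        except ValueError as exc:
            log.warning("skipping %s: %s", ind, exc)
            continue
        write_ascii_grid(outdir / f"ud_{ind}.asc", ud.ud, grid)
        index_rows.append({"individual": ind, "season": season, "class": cls,
                           "n_fixes": ud.n_fixes,
                           "n_parts": ud.n_isopleth_parts,
                           "h_x": float(np.sqrt(ud.bandwidth[0, 0])),
                           "h_y": float(np.sqrt(ud.bandwidth[1, 1]))})
        for poly in ud.isopleths:
            polys.append(poly)
            props.append({"individual": ind, "season": season, "class": cls})
    pd.DataFrame(index_rows).to_csv(outdir / "ud_index.csv", index=False)
    write_geojson(outdir / "isopleths.geojson", polys, props)
    return _write_manifest(outdir, "homerange", [outdir / "telemetry.csv"],
                           [outdir / "ud_index.csv", outdir / "isopleths.geojson"],
                           config)


def stage_rsf(outdir, config: RunConfig,
              covariate_names: list[str] | None = None) -> Path:
    """Used-available design, mixed-model fit, reports, and class maps."""
    outdir = Path(outdir)
    names = covariate_names or ENV_LAYERS
    stack = _load_stack(outdir, names)
    clean = pd.read_csv(outdir / "telemetry_clean.csv",
                        parse_dates=["timestamp"])
    index = pd.read_csv(outdir / "ud_index.csv")
    geoms, props = read_geojson(outdir / "isopleths.geojson")
    used, range_info = {}, {}
    for _, row in index.iterrows():
        rid = f"{row['individual']}:{row['season']}"
        grp = clean[clean["individual"] == row["individual"]]
        used[rid] = grp
        poly = [g for g, p in zip(geoms, props) if p["individual"] == row["individual"]]
        range_info[rid] = {"polygons": poly, "individual": row["individual"],
                           "class": row["class"]}
    design, record = rsfmod.build_design(used, range_info, stack, names,
                                         ratio=config.ratio, seed=config.seed + 41)
    kept, vifs = cov.vif_prune(design[names], threshold=config.vif_threshold)
    if set(kept) != set(names):
        log.info("VIF pruning dropped %s", sorted(set(names) - set(kept)))
    design.to_csv(outdir / "rsf_design.csv", index=False)
    vifs.to_csv(outdir / "rsf_vif.csv")

    fixed = [*kept, "class", ("precipitation", "class")] \
        if "precipitation" in kept else [*kept, "class"]
    random = RandomSpec(group="range_id", intercept=True)
    deletion, final_terms, final = rsfmod.lrt_term_deletion(
        design, fixed, random, alpha=config.alpha)
    r2 = rsfmod.r2_nakagawa(final, design)
    table = rsfmod.fixed_effects_table(final, deletion, r2)
    table.to_csv(outdir / "rsf_fixed_effects.csv")
    deletion.to_csv(outdir / "rsf_lrt.csv", index=False)
    (outdir / "rsf_model_stats.json").write_text(json.dumps(
        {"aic": final.aic, "r2_marginal": r2[0], "r2_conditional": r2[1],
         "terms": [str(t) for t in final_terms],
         "re_variances": final.re_variances}))

    zmap = cov.standardize_with_record(stack, record)
    outputs = [outdir / "rsf_fixed_effects.csv", outdir / "rsf_lrt.csv"]
    for cls in synth.DEMOGRAPHIC_CLASSES:
        w = rsfmod.predict_rsf_map(final, zmap, cls)
        p = outdir / f"map_{cls.replace(' ', '_')}.asc"
        write_ascii_grid(p, w, stack.grid)
        outputs.append(p)
    return _write_manifest(outdir, "rsf",
                           [outdir / "telemetry_clean.csv", outdir / "ud_index.csv"],
                           outputs, config)


def stage_report(outdir) -> pd.DataFrame:
    """Human-readable summary table for a completed run."""
    outdir = Path(outdir)
    path = outdir / "rsf_fixed_effects.csv"
    if not path.exists():
        raise FileNotFoundError("rsf stage has not completed; no fixed-effects table")
    table = pd.read_csv(path, index_col=0)
    stats = json.loads((outdir / "rsf_model_stats.json").read_text())
    lines = [table.to_string(),
             f"AIC {stats['aic']:.1f} | Marginal R2 {stats['r2_marginal']:.2f} | "
             f"Conditional R2 {stats['r2_conditional']:.2f}"]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return table


def run_all(outdir, config: RunConfig | None = None, n_per_class: int = 2,
            n_days: int | None = 90) -> None:
    config = config or RunConfig()
    stage_simulate(outdir, config, n_per_class=n_per_class, n_days=n_days)
    stage_occupancy(outdir, config)
    stage_homerange(outdir, config)
    stage_rsf(outdir, config)
    stage_report(outdir)
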