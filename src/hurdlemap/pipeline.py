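"""End-to-end orchestration: simulate → prep → sets → SDM → SAM → prioritize.

Every stage derives its random stream from the run seed, logs record-count
deltas, and persists its artifacts, so a rerun with the same configuration is
byte-identical. A stage failure aborts the run with the stage name and cause;
whatever was already written is flagged as partial in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import occurrences as occ
from . import predictors as pred
from . import priority as pri
from . import suitability as suit
from .config import RunConfig
from .grid import PredictorStack
from .io import read_geojson, read_raster, read_table, write_geojson, write_raster, write_table
from .synth import SyntheticDataset, default_scenario, generate_dataset

log = logging.getLogger(__name__)

SDM_SPECS = [suit.SDMSpec("GLM", False), suit.SDMSpec("GLM", True),
             suit.SDMSpec("GAM", False), suit.SDMSpec("GAM", True)]


# ---------------------------------------------------------------------------
# dataset persistence (used by the `simulate` CLI subcommand and input_dir)
# ---------------------------------------------------------------------------

def save_dataset(ds: SyntheticDataset, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"layers": ds.stack.names, "types": ds.stack.types,
            "species": list(ds.occurrences)}
    for name in ds.stack.names:
        write_raster(ds.stack[name], outdir / f"layer_{name}.asc", dtype="float")
    for sp, df in ds.occurrences.items():
        write_table(df, outdir / f"occurrences_{sp}.csv")
    for sp, df in ds.transects.items():
        write_table(df, outdir / f"transects_{sp}.csv")
    write_geojson(ds.range_polygon, outdir / "range.geojson")
    write_geojson(ds.protected_areas, outdir / "protected_areas.geojson")
    write_geojson(list(ds.zones.values()), outdir / "zones.geojson",
                  properties=[{"name": k} for k in ds.zones])
    truth = {sp: {"beta_occ": t.beta_occ, "beta_abu": t.beta_abu,
                  "family": t.family, "theta": t.theta}
             for sp, t in ds.truth.items()}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    (outdir / "dataset.json").write_text(json.dumps(meta, indent=1))
    return outdir


def load_dataset(indir) -> SyntheticDataset:
    indir = Path(indir)
    meta = json.loads((indir / "dataset.json").read_text())
    layers = {n: read_raster(indir / f"layer_{n}.asc") for n in meta["layers"]}
    stack = PredictorStack(layers, meta["types"])
    occurrences = {sp: read_table(indir / f"occurrences_{sp}.csv")
                   for sp in meta["species"]}
    transects = {sp: read_table(indir / f"transects_{sp}.csv")
                 for sp in meta["species"]}
    range_polygon = read_geojson(indir / "range.geojson")[0][0]
    pas = read_geojson(indir / "protected_areas.geojson")[0]
    zg, zp = read_geojson(indir / "zones.geojson")
    zones = {p.get("name", f"zone_{i}"): g for i, (g, p) in enumerate(zip(zg, zp))}
    return SyntheticDataset(config=None, stack=stack, occurrences=occurrences,
                            transects=transects, range_polygon=range_polygon,
                            protected_areas=pas, zones=zones, truth={})


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _mask_stack_to_area(stack: PredictorStack, polygon) -> PredictorStack:
    from shapely import contains_xy
    xs, ys = stack.grid.cell_centers()
    outside = ~contains_xy(polygon, xs.ravel(), ys.ravel()).reshape(stack.grid.shape)
    layers = {}
    for n in stack.names:
        lyr = stack[n]
        layers[n] = lyr.like(np.ma.masked_where(outside | lyr.mask,
                                                np.ma.getdata(lyr.values)))
    return PredictorStack(layers, dict(stack.types))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full two-species workflow; returns (and writes) the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict = {"config": asdict(config), "stages": {}, "species": {},
                    "partial": True}
    stage = "init"
    try:
        stage = "data"
        if config.input_dir:
            ds = load_dataset(config.input_dir)
        else:
            scenario = default_scenario(seed=config.seed,
                                        shape=tuple(config.grid_shape),
                                        n_occurrences=config.n_occurrences,
                                        n_transects=config.n_transects)
            ds = generate_dataset(scenario)
            save_dataset(ds, outdir / "dataset")
        species = list(ds.occurrences)
        if len(species) != 2:
            raise ValueError(f"prioritization needs exactly 2 species, got "
                             f"{len(species)}")
        root = np.random.SeedSequence(config.seed)
        sp_keys = {sp: root.spawn(1)[0] for sp in species}
        report["stages"]["data"] = {
            "n_layers": len(ds.stack), "species": species,
            "occurrences": {sp: len(df) for sp, df in ds.occurrences.items()},
            "transect_records": {sp: len(df) for sp, df in ds.transects.items()}}

        stage = "heterogeneity"
        het = occ.heterogeneity_raster(ds.stack)

        presence_maps, abundant_maps = {}, {}
        suitability_maps, abundance_maps = {}, {}
        for sp in species:
            keys = sp_keys[sp].spawn(8)
            spdir = outdir / sp
            spdir.mkdir(exist_ok=True)
            sp_report: dict = {}

            stage = f"{sp}:clean"
            cleaned, creport = occ.clean_occurrences(
                ds.occurrences[sp], min_year=config.min_year,
                max_uncertainty_km=config.max_uncertainty_km,
                range_polygon=ds.range_polygon)
            sp_report["cleaning"] = {"input": creport.input_count,
                                     "removals": creport.removals,
                                     "output": creport.output_count}

            stage = f"{sp}:thin"
            thinned = occ.thin_to_pixel_centroids(cleaned, ds.stack.grid)
            stage = f"{sp}:rarefy"
            rarefied = occ.rarefy_by_heterogeneity(
                thinned, het, distances_km=config.rarefy_distances_km,
                seed=np.random.default_rng(keys[0]))
            sp_report["records"] = {"cleaned": len(cleaned),
                                    "thinned": len(thinned),
                                    "rarefied": len(rarefied)}
            write_table(rarefied, spdir / "occurrences_prepared.csv")

            stage = f"{sp}:calibration_area"
            calib = occ.build_calibration_area(
                rarefied, config.hull_km, config.buffer_km, ds.range_polygon)
            write_geojson(calib.polygon, spdir / "calibration_area.geojson")
            area_stack = _mask_stack_to_area(ds.stack, calib.polygon)

            stage = f"{sp}:pseudo_absences"
            pas = occ.sample_pseudo_absences(
                calib, ds.stack.grid, rarefied, n=config.n_pseudo_absences,
                seed=np.random.default_rng(keys[1]))
            write_table(pas, spdir / "pseudo_absences.csv")
            sp_report["n_pseudo_absences"] = len(pas)

            stage = f"{sp}:predictor_sets"
            sets = pred.build_sets(area_stack, r_threshold=config.r_threshold,
                                   n_cells=config.correlation_sample_cells,
                                   seed=np.random.default_rng(keys[2]))
            (spdir / "predictor_sets.json").write_text(json.dumps(
                [{"set_id": s.set_id, "input": s.input_members,
                  "members": s.members, "log": s.pruning_log} for s in sets],
                indent=1, default=str))
            sp_report["n_predictor_sets"] = len(sets)

            stage = f"{sp}:sdm"
            pres_xy = rarefied[["x", "y"]].to_numpy(float)
            pa_xy = pas[["x", "y"]].to_numpy(float)
            all_xy = np.vstack([pres_xy, pa_xy])
            y = np.r_[np.ones(len(pres_xy)), np.zeros(len(pa_xy))]
            X_all = np.ma.getdata(ds.stack.extract(all_xy[:, 0], all_xy[:, 1]))
            rng_cv = np.random.default_rng(keys[3])
            rows = []
            best = None
            for s in sets:
                cols = [ds.stack.names.index(m) for m in s.members]
                Xs = X_all[:, cols]
                for spec in SDM_SPECS:
                    em = suit.crossval(spec, Xs, y, s.members,
                                       folds=config.cv_folds,
                                       calib_frac=config.calib_frac,
                                       seed=rng_cv, auc_min=config.auc_min,
                                       tss_min=config.tss_min)
                    rows.append({"set": s.set_id, "model": spec.label,
                                 "auc": em.auc_mean, "tss": em.tss_mean,
                                 "threshold": em.threshold,
                                 "passes": em.passes})
                    key = (em.passes, em.tss_mean, em.auc_mean)
                    if best is None or key > best[0]:
                        best = (key, s, spec, em)
            metrics = pd.DataFrame(rows)
            write_table(metrics, spdir / "sdm_metrics.csv")
            _, best_set, best_spec, best_eval = best
            sp_report["sdm"] = {
                "n_models": len(rows),
                "n_passing": int(metrics["passes"].sum()),
                "best": {"set": best_set.set_id, "model": best_spec.label,
                         "auc": best_eval.auc_mean, "tss": best_eval.tss_mean,
                         "threshold": best_eval.threshold,
                         "passes": best_eval.passes}}

            stage = f"{sp}:sdm_projection"
            cols = [ds.stack.names.index(m) for m in best_set.members]
            sdm_model = best_spec.fit(X_all[:, cols], y, best_set.members)
            suit_map = suit.project_suitability(sdm_model, area_stack)
            presence = suit.binarize(suit_map, best_eval.threshold)
            write_raster(suit_map, spdir / "suitability.asc", dtype="float")
            write_raster(presence, spdir / "presence.asc", dtype="int")
            suitability_maps[sp] = suit_map
            presence_maps[sp] = presence

            stage = f"{sp}:sam"
            tr = ds.transects[sp]
            Xt_all = np.ma.getdata(ds.stack.extract(tr["x"].to_numpy(float),
                                                    tr["y"].to_numpy(float)))
            counts = tr["count"].to_numpy(float)
            lengths = tr["length_km"].to_numpy(float)
            passing_sets = [s for s in sets
                            if metrics.loc[metrics["set"] == s.set_id,
                                           "passes"].any()] or [best_set]
            rng_sam = np.random.default_rng(keys[4])
            sam_rows = []
            best_sam = None
            for s in passing_sets:
                cols = [ds.stack.names.index(m) for m in s.members]
                for method in ("GLM", "GAM"):
                    model = ab.fit_abundance(
                        Xt_all[:, cols], counts, lengths, s.members,
                        family=config.abundance_family, method=method,
                        n_boot=config.n_boot_fit, seed=rng_sam,
                        k=config.gam_k, select=(method == "GAM"),
                        drop_zeros=(config.abundance_family == "gamma"))
                    predicted = model.predict(Xt_all[:, cols], lengths)
                    rep = ab.consistency(counts, predicted,
                                         r_min=config.consistency_r_min)
                    sam_rows.append({"set": s.set_id, "model": method,
                                     "r": rep.r, "slope": rep.slope,
                                     "intercept": rep.intercept,
                                     "explained_deviance":
                                         model.explained_deviance,
                                     "passes": rep.passes})
                    key = (rep.passes, rep.r)
                    if best_sam is None or key > best_sam[0]:
                        best_sam = (key, s, model, rep)
            sam_metrics = pd.DataFrame(sam_rows)
            write_table(sam_metrics, spdir / "sam_metrics.csv")
            _, sam_set, sam_model, sam_rep = best_sam
            write_table(sam_model.boot_coef, spdir / "sam_boot_coef.csv")
            sp_report["sam"] = {
                "n_models": len(sam_rows),
                "n_passing": int(sam_metrics["passes"].sum()),
                "best": {"set": sam_set.set_id, "model": sam_model.method,
                         "r": sam_rep.r, "slope": sam_rep.slope,
                         "explained_deviance": sam_model.explained_deviance,
                         "n_boot": sam_model.n_boot}}

            stage = f"{sp}:abundance_projection"
            amap_raw = ab.project_abundance(sam_model, area_stack, presence)
            fences = ab.inner_fences(amap_raw.raster.values.compressed(),
                                     n_boot=config.n_boot_fence,
                                     seed=np.random.default_rng(keys[5]),
                                     variant=config.fence_variant)
            sp_report["fences"] = {"lower": fences.lower, "upper": fences.upper}
            amaps = {p: ab.apply_policy(amap_raw, fences, p)
                     for p in ("no_extrapolation", "extrapolation_and_clamping")}
            write_raster(amap_raw.raster, spdir / "abundance_raw.asc",
                         dtype="float")
            for p, m in amaps.items():
                write_raster(m.raster, spdir / f"abundance_{p}.asc",
                             dtype="float")

            stage = f"{sp}:relationship"
            rel_report = {}
            rng_rel = np.random.default_rng(keys[6])
            for p, m in amaps.items():
                rescaled = pri.rescale01(m.raster)
                rel = pri.spatial_correlation(
                    suit_map, rescaled, sample_frac=config.correlation_sample_frac,
                    seed=rng_rel, method="best_models", policy=p)
                rel_report[p] = {"r": rel.r, "p_value": rel.p_value,
                                 "ci95": rel.ci95, "n_cells": rel.n_cells}
            sp_report["relationship"] = rel_report

            chosen = amaps[config.extrapolation_policy]
            abundance_maps[sp] = chosen
            abundant_maps[sp] = pri.binarize_abundance_median(chosen.raster)
            write_raster(abundant_maps[sp], spdir / "abundant_binary.asc",
                         dtype="int")
            report["species"][sp] = sp_report

        stage = "consensus"
        a, b = species
        pm = pri.consensus(presence_maps[a], abundant_maps[a],
                           presence_maps[b], abundant_maps[b])
        write_raster(pm.raster, outdir / "priority.asc", dtype="int")
        cat_areas = pm.category_areas_km2()
        prioritized = sum(v for k, v in cat_areas.items() if k != "none")
        report["stages"]["consensus"] = {
            "category_areas_km2": cat_areas,
            "prioritized_km2": prioritized,
            "category_pct": {k: (100.0 * v / prioritized if prioritized else 0.0)
                             for k, v in cat_areas.items() if k != "none"}}

        stage = "critical_areas"
        crit = pri.critical_areas(pm)
        if not crit.polygon.is_empty:
            write_geojson(crit.polygon, outdir / "critical_areas.geojson")
        prot, unprot, frac = pri.protected_overlap(crit, ds.protected_areas)
        report["stages"]["critical"] = {
            "critical_km2": crit.area_km2, "protected_km2": prot,
            "unprotected_km2": unprot, "protected_fraction": frac}

        stage = "area_accounting"
        areas = pri.area_accounting(pm, ds.zones)
        write_table(areas.reset_index(names="category"), outdir / "areas.csv")
        report["stages"]["areas_km2"] = json.loads(areas.to_json())

        report["partial"] = False
    except Exception as e:
        report["failed_stage"] = stage
        report["error"] = str(e)
        (outdir / "report.json").write_text(json.dumps(report, indent=1,
                                                       default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    log.info("pipeline finished: %s", outdir)
    return report
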