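"""Orchestration of the full analysis from one run configuration.

Stages communicate through files in the run directory so each can be run
(and tested) independently:

    simulate   env_present.tif, env_<scenario>.tif, occurrences.csv, truth_<sp>.tif
    prep       occurrences_thinned.csv, vif_report.csv, variables.json,
               training_ranges.json, min_records.csv
    fit        models/<species>.joblib, metrics.csv
    evaluate   retained.json
    project    ensembles/<species>_<scenario>.npz, anova_samples.csv
    stack      stacks/<pft>_<scenario>_{richness,bssdm,presence}.tif
    dominate   dominance_<scenario>.tif, area_fractions.csv, flows_<scenario>.csv
    shift      shifts.csv
    fragment   fragmentation/<pft>_<scenario>.tif, fragmentation_summary.csv
    partition  uncertainty.csv, factor_ranking.csv

``run_pipeline`` executes them in order and writes ``manifest.json`` with
seeds, thresholds, per-stage wall times and output digests; a rerun with
the same configuration reproduces the digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import (
    data_prep,
    dominance,
    evaluation,
    fragmentation,
    raster_io,
    sdm_ensemble,
    shifts,
    stacking,
    uncertainty,
)
from .config import RunConfig, derive_seed
from .synthetic_landscape import apply_climate_delta, generate_landscape, sample_occurrences, true_suitability

log = logging.getLogger("pftshift")

PRESENT = "present"

STAGES = [
    "simulate",
    "prep",
    "fit",
    "evaluate",
    "project",
    "stack",
    "dominate",
    "shift",
    "fragment",
    "partition",
]


def _scenario_labels(cfg: RunConfig) -> list[str]:
    return [PRESENT] + [s.label for s in cfg.scenarios]


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    out = raster_io.ensure_dir(out)
    env = generate_landscape(cfg.grid, cfg.landscape, seed=derive_seed(cfg.seed, "landscape"))
    raster_io.write_stack(out / "env_present.tif", env)
    for sc in cfg.scenarios:
        raster_io.write_stack(out / f"env_{sc.label}.tif", apply_climate_delta(env, sc.delta))
    records = []
    for sid, niche in cfg.niches.items():
        occ = sample_occurrences(
            env, niche, n=cfg.n_records[sid], seed=derive_seed(cfg.seed, "occ", sid)
        )
        records.append(pd.DataFrame({"species": occ.species, "lon": occ.lon, "lat": occ.lat}))
        raster_io.write_grid(
            out / f"truth_{sid}.tif", true_suitability(env, niche), cfg.grid, name="truth"
        )
    pd.concat(records, ignore_index=True).to_csv(out / "occurrences.csv", index=False)
    log.info("simulate: %d species, %d scenarios", len(cfg.niches), len(cfg.scenarios))


def stage_prep(cfg: RunConfig, out: Path) -> None:
    env = raster_io.read_stack(out / "env_present.tif")
    occ = raster_io.read_occurrences(out / "occurrences.csv")
    thinned = data_prep.thin_to_grid(occ, env.grid)
    raster_io.write_occurrences(out / "occurrences_thinned.csv", thinned)

    report = data_prep.check_min_records(thinned, minimum=int(cfg.threshold("min_records")))
    report.to_csv(out / "min_records.csv", index=False)
    failing = report.loc[~report["passed"], "species"].tolist()
    if failing and not cfg.model_param("allow_below_min"):
        raise RuntimeError(
            f"species below the minimum record count: {failing}; "
            "set modelling.allow_below_min to override"
        )

    # pooled presence + background sample for collinearity screening
    rng = np.random.default_rng(derive_seed(cfg.seed, "vif_background"))
    pr, pc = env.grid.cell_of(thinned.lon, thinned.lat)
    valid_idx = np.flatnonzero(~env.mask.ravel())
    n_bg = min(int(cfg.model_param("n_background_vif")), valid_idx.size)
    bg = rng.choice(valid_idx, size=n_bg, replace=False)
    br, bc = np.unravel_index(bg, env.grid.shape)
    rows = np.concatenate([pr, br])
    cols = np.concatenate([pc, bc])
    sample = pd.DataFrame({v: env.layers[v][rows, cols] for v in env.layer_names})
    screen = data_prep.vif_stepwise(sample, threshold=float(cfg.threshold("vif")))
    screen.report().to_csv(out / "vif_report.csv", index=False)
    (out / "variables.json").write_text(json.dumps(screen.retained))
    ranges = data_prep.training_ranges(env, screen.retained)
    (out / "training_ranges.json").write_text(json.dumps(ranges))
    log.info("prep: %d/%d records kept, retained predictors %s",
             len(thinned), len(occ), screen.retained)


def stage_fit(cfg: RunConfig, out: Path) -> None:
    env = raster_io.read_stack(out / "env_present.tif")
    occ = raster_io.read_occurrences(out / "occurrences_thinned.csv")
    variables = json.loads((out / "variables.json").read_text())
    models_dir = raster_io.ensure_dir(out / "models")
    metric_rows = []
    for sid in cfg.niches:
        occ_s = occ.subset(sid)
        pres = np.nonzero(sdm_ensemble.presence_cells(occ_s, env))
        fits: list[sdm_ensemble.ReplicateFit] = []
        for spec in cfg.learners:
            pa = sdm_ensemble.draw_pseudo_absences(
                env, occ_s, spec, seed=derive_seed(cfg.seed, "pa", sid, spec.name)
            )
            fits.extend(
                sdm_ensemble.fit_replicates(
                    spec,
                    pres,
                    pa,
                    env,
                    variables,
                    species_id=sid,
                    n_replicates=int(cfg.model_param("n_replicates")),
                    train_frac=float(cfg.model_param("train_frac")),
                    seed=derive_seed(cfg.seed, "fit", sid),
                )
            )
        joblib.dump(fits, models_dir / f"{sid}.joblib")
        for f in fits:
            metric_rows.append(
                (sid, f.learner, f.replicate, f.metrics.auc, f.metrics.cbi,
                 np.nan if f.metrics.calibration is None else f.metrics.calibration)
            )
        log.info("fit: %s -> %d replicate fits", sid, len(fits))
    pd.DataFrame(
        metric_rows, columns=["species", "learner", "replicate", "auc", "cbi", "cal"]
    ).to_csv(out / "metrics.csv", index=False)


def stage_evaluate(cfg: RunConfig, out: Path) -> None:
    metrics = pd.read_csv(out / "metrics.csv")
    presence_only = {s.name for s in cfg.learners if s.presence_only}
    retained: dict[str, list[str]] = {}
    for sid, grp in metrics.groupby("species"):
        per_learner = {}
        for name, g in grp.groupby("learner"):
            per_learner[name] = evaluation.EvaluationMetrics(
                auc=float(g["auc"].mean()),
                cbi=float(g["cbi"].mean()),
                calibration=None if g["cal"].isna().all() else float(g["cal"].mean()),
                n_presences=0,
                n_absences=0,
            )
        retained[sid] = evaluation.filter_models(
            per_learner, threshold=float(cfg.threshold("filter")),
            presence_only=presence_only,
        )
        log.info("evaluate: %s retained %s", sid, retained[sid])
    (out / "retained.json").write_text(json.dumps(retained))


def stage_project(cfg: RunConfig, out: Path) -> None:
    retained = json.loads((out / "retained.json").read_text())
    ranges = {k: tuple(v) for k, v in json.loads((out / "training_ranges.json").read_text()).items()}
    ens_dir = raster_io.ensure_dir(out / "ensembles")
    labels = _scenario_labels(cfg)
    stacks = {}
    for label in labels:
        src = "env_present.tif" if label == PRESENT else f"env_{label}.tif"
        stacks[label] = data_prep.clamp_to_range(raster_io.read_stack(out / src), ranges).clamped

    rng = np.random.default_rng(derive_seed(cfg.seed, "anova_cells"))
    valid = np.flatnonzero(~stacks[PRESENT].mask.ravel())
    n_cells = min(int(cfg.model_param("anova_cells")), valid.size)
    cell_idx = np.sort(rng.choice(valid, size=n_cells, replace=False))
    cr, cc = np.unravel_index(cell_idx, cfg.grid.shape)
    scenario_tags = {s.label: (s.rcp, s.gcm) for s in cfg.scenarios}
    anova_rows = []

    for sid in cfg.niches:
        fits = joblib.load(out / "models" / f"{sid}.joblib")
        keep = [f for f in fits if f.learner in retained[sid]]
        if not keep:
            raise RuntimeError(f"no retained learners for species {sid!r}")
        k = min(int(cfg.model_param("k_projection")),
                min(sum(f.learner == ln for f in keep) for ln in retained[sid]))
        sel = sdm_ensemble.select_projection_replicates(
            keep, k=k, seed=derive_seed(cfg.seed, "select", sid)
        )
        thresholds = {}
        for name in retained[sid]:
            grp = [f for f in sel if f.learner == name]
            pooled_scores = np.concatenate([f.holdout_scores for f in grp])
            pooled_labels = np.concatenate([f.holdout_labels for f in grp])
            thresholds[name] = stacking.max_sss_threshold(pooled_scores, pooled_labels)
        for label in labels:
            env = stacks[label]
            learner_maps = {}
            all_maps = []
            for name in retained[sid]:
                maps = [sdm_ensemble.predict_map(f, env) for f in sel if f.learner == name]
                learner_maps[name] = sdm_ensemble.ensemble_mean(maps)
                all_maps.extend(maps)
                if label in scenario_tags:
                    rcp, gcm = scenario_tags[label]
                    for f, m in zip([f for f in sel if f.learner == name], maps):
                        vals = m[cr, cc]
                        for ci in range(n_cells):
                            anova_rows.append(
                                (sid, name, f.replicate, rcp, gcm, ci, vals[ci])
                            )
            overall = sdm_ensemble.ensemble_mean(all_maps)
            np.savez_compressed(
                ens_dir / f"{sid}_{label}.npz",
                overall=overall,
                learners=np.array(retained[sid], dtype=object),
                thresholds=np.array([thresholds[n] for n in retained[sid]]),
                **{f"map_{n}": learner_maps[n] for n in retained[sid]},
            )
        log.info("project: %s (%d learners x %d replicates)", sid, len(retained[sid]), k)
    pd.DataFrame(
        anova_rows,
        columns=["species", "algorithm", "replicate", "rcp", "gcm", "cell", "value"],
    ).to_csv(out / "anova_samples.csv", index=False)


def _load_ensemble(out: Path, sid: str, label: str):
    z = np.load(out / "ensembles" / f"{sid}_{label}.npz", allow_pickle=True)
    learners = list(z["learners"])
    thresholds = list(z["thresholds"])
    learner_maps = [z[f"map_{n}"] for n in learners]
    return z["overall"], learner_maps, thresholds


def stage_stack(cfg: RunConfig, out: Path) -> None:
    stacks_dir = raster_io.ensure_dir(out / "stacks")
    min_agree = int(cfg.threshold("min_agree"))
    presence_min = int(cfg.threshold("presence_min"))
    for label in _scenario_labels(cfg):
        for pft, members in cfg.pfts.items():
            prob_maps, bin_maps = [], []
            for sid in members:
                overall, learner_maps, thresholds = _load_ensemble(out, sid, label)
                prob_maps.append(overall)
                bin_maps.append(
                    stacking.binarize_species(learner_maps, thresholds, min_agree=min_agree)
                )
            res = stacking.build_pft_result(pft, members, prob_maps, bin_maps, presence_min)
            raster_io.write_grid(stacks_dir / f"{pft}_{label}_richness.tif", res.richness, cfg.grid, "richness")
            raster_io.write_grid(stacks_dir / f"{pft}_{label}_bssdm.tif", res.bssdm, cfg.grid, "bssdm")
            raster_io.write_grid(
                stacks_dir / f"{pft}_{label}_presence.tif",
                res.presence.astype(float), cfg.grid, "presence",
            )
    log.info("stack: wrote %d PFT x scenario stacks", len(cfg.pfts) * len(_scenario_labels(cfg)))


def _load_pft_result(cfg: RunConfig, out: Path, pft: str, label: str) -> stacking.PFTResult:
    stacks_dir = out / "stacks"
    rich, *_ = raster_io.read_grid(stacks_dir / f"{pft}_{label}_richness.tif")
    bssdm, *_ = raster_io.read_grid(stacks_dir / f"{pft}_{label}_bssdm.tif")
    pres, *_ = raster_io.read_grid(stacks_dir / f"{pft}_{label}_presence.tif")
    return stacking.PFTResult(
        pft=pft, members=cfg.pfts[pft], richness=rich, bssdm=bssdm,
        presence=pres > 0.5, presence_min=int(cfg.threshold("presence_min")),
    )


def _dominance_map(cfg: RunConfig, out: Path, label: str) -> dominance.DominanceMap:
    order = list(cfg.pfts)
    results = [_load_pft_result(cfg, out, p, label) for p in order]
    return dominance.dominant_pft(results, order=order)


def stage_dominate(cfg: RunConfig, out: Path) -> None:
    areas = dominance.cell_areas(cfg.grid)
    frames = []
    doms = {label: _dominance_map(cfg, out, label) for label in _scenario_labels(cfg)}
    for label, dom in doms.items():
        codes = np.full(dom.shape, -1.0)
        for i, cls in enumerate(dom.classes):
            codes[dom.labels == cls] = i
        raster_io.write_grid(
            out / f"dominance_{label}.tif", codes, cfg.grid, "dominance",
            class_table=dict(enumerate(dom.classes)),
        )
        af = dominance.area_fractions(dom, areas)
        af.insert(0, "scenario", label)
        frames.append(af)
        if int(dom.ties.sum()):
            log.warning("dominate: %d tie cells in %s", int(dom.ties.sum()), label)
    pd.concat(frames, ignore_index=True).to_csv(out / "area_fractions.csv", index=False)
    for sc in cfg.scenarios:
        flows = dominance.transition_flows(doms[PRESENT], doms[sc.label], areas)
        flows.to_csv(out / f"flows_{sc.label}.csv")
    log.info("dominate: wrote dominance maps and flows")


def stage_shift(cfg: RunConfig, out: Path) -> None:
    env = raster_io.read_stack(out / "env_present.tif")
    elev = env.layers["elevation"]
    q = float(cfg.threshold("quantile"))
    rows = []
    for pft in cfg.pfts:
        pres_pts = {}
        for label in _scenario_labels(cfg):
            mask, *_ = raster_io.read_grid(out / "stacks" / f"{pft}_{label}_presence.tif")
            pres_pts[label] = shifts.presence_lat_alt(mask > 0.5, elev, cfg.grid)
        base = pres_pts[PRESENT]
        for label in _scenario_labels(cfg):
            pts = pres_pts[label]
            if len(base) and len(pts):
                shift = shifts.boundary_shift(base, pts, quantile=q)
                lower = float(np.quantile(pts["alt"], q))
                n_modes, locs = (
                    shifts.latitudinal_modes(pts, bandwidth=0.5) if len(pts) >= 2 else (0, [])
                )
            else:
                shift, lower, n_modes, locs = np.nan, np.nan, 0, []
            rows.append(
                (pft, label, lower, shift, n_modes,
                 ";".join(f"{x:.3f}" for x in np.asarray(locs)))
            )
    pd.DataFrame(
        rows,
        columns=["pft", "scenario", "lower_boundary_m", "shift_m", "n_modes", "mode_lats"],
    ).to_csv(out / "shifts.csv", index=False)
    log.info("shift: wrote shift summary")


def stage_fragment(cfg: RunConfig, out: Path) -> None:
    frag_dir = raster_io.ensure_dir(out / "fragmentation")
    areas = dominance.cell_areas(cfg.grid)
    doms = {label: _dominance_map(cfg, out, label) for label in _scenario_labels(cfg)}
    frames = []
    for pft in cfg.pfts:
        baseline = doms[PRESENT].labels == pft
        for label in _scenario_labels(cfg):
            now = doms[label].labels == pft
            pf, pff = fragmentation.pf_pff(now.astype(float))
            frag = fragmentation.classify(
                pf, pff, now, presence_baseline=baseline, pft=pft, scenario=label
            )
            raster_io.write_grid(
                frag_dir / f"{pft}_{label}.tif", frag.codes.astype(float), cfg.grid,
                "fragmentation", class_table=dict(enumerate(fragmentation.CLASS_NAMES)),
            )
            summ = fragmentation.class_summary(frag, areas)
            summ.insert(0, "scenario", label)
            summ.insert(0, "pft", pft)
            frames.append(summ)
    pd.concat(frames, ignore_index=True).to_csv(out / "fragmentation_summary.csv", index=False)
    log.info("fragment: wrote fragmentation maps and summary")


def stage_partition(cfg: RunConfig, out: Path) -> None:
    samples = pd.read_csv(out / "anova_samples.csv")
    parts = []
    rows = []
    for (sid, cell), grp in samples.groupby(["species", "cell"]):
        part = uncertainty.anova_partition(grp)
        parts.append(part)
        rows.append((sid, cell, *[part.fractions[f] for f in uncertainty.FACTORS],
                     part.residual, part.degenerate))
    pd.DataFrame(
        rows,
        columns=["species", "cell", *uncertainty.FACTORS, "residual", "degenerate"],
    ).to_csv(out / "uncertainty.csv", index=False)
    ranking = uncertainty.rank_factors([p for p in parts if not p.degenerate] or parts)
    ranking.to_csv(out / "factor_ranking.csv", index=False)
    log.info("partition: factor ranking %s", list(ranking["factor"]))


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "fit": stage_fit,
    "evaluate": stage_evaluate,
    "project": stage_project,
    "stack": stage_stack,
    "dominate": stage_dominate,
    "shift": stage_shift,
    "fragment": stage_fragment,
    "partition": stage_partition,
}

#: files digested into the manifest (deterministic outputs)
_DIGEST_FILES = [
    "occurrences.csv",
    "occurrences_thinned.csv",
    "vif_report.csv",
    "variables.json",
    "metrics.csv",
    "retained.json",
    "area_fractions.csv",
    "shifts.csv",
    "fragmentation_summary.csv",
    "factor_ranking.csv",
]


def run_pipeline(cfg: RunConfig, out) -> dict:
    """Run every stage in order; return (and write) the run manifest."""
    cfg.validate()
    out = raster_io.ensure_dir(out)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": {k: cfg.threshold(k)
                       for k in ("vif", "filter", "min_agree", "presence_min", "quantile", "min_records")},
        "stages": [],
    }
    for name in STAGES:
        t0 = time.perf_counter()
        try:
            STAGE_FUNCS[name](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"name": name, "seconds": round(time.perf_counter() - t0, 3)})
    digests = {}
    for fname in _DIGEST_FILES:
        p = out / fname
        if p.exists():
            digests[fname] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest["digests"] = digests
    (Path(out) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
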