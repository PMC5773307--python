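"""End-to-end orchestration of the six analysis stages from one config.

Stage order: synth -> studyarea -> (occurrence, evi) -> classify -> keyhab.
Every stage writes text artifacts (ESRI ASCII grids, CSV, JSON) into the
output directory and records them in an append-only manifest with SHA-256
checksums; a rerun with the same config and seed reproduces the checksums
of deterministic artifacts.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, evi, keyhab, occurrence as occ, studyarea, synth
from .grid import BinaryMask, GridLayer, write_ascii_grid

log = logging.getLogger(__name__)

STAGES = ("synth", "studyarea", "occurrence", "evi", "classify", "keyhab")

#: Demo-profile defaults. Study-area bounds are calibrated to the synthetic
#: layer distributions (the module-level defaults in
#: :mod:`keyhabitat.studyarea` describe real-world layers whose ranges a
#: smoothed-noise field occupies very differently). The full-scale profile
#: raises n_trees to 50,000.
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "scratch/run",
    "synth": {
        "coarse_shape": [60, 60],
        "refine_factor": 4,
        "layers": ["ELEV", "TREE", "AI"],
        "n_presences": 600,
        "n_points": 90,
        "stops": 3,
        "spacing_m": 500.0,
        "n_discard": 79,
        "label_noise": 0.1,
        "evi_start": "2000-02-02",
        "evi_end": "2015-06-30",
    },
    "studyarea": {
        "elev": [200.0, 2800.0],
        "tree": [10.0, 100.0],
        "ai": [5000.0, 20000.0],
    },
    "occurrence": {
        "formulas": {"mdl3": ["TREE", "AI"]},
        "skewed": [],
        "frac": 0.75,
        "n_replicates": 5,
        "n_pseudoabsences": 88,
        "n_selected": 3,
        "min_records": 30,
    },
    "evi": {"min_seg": 4, "penalty": "mbic"},
    "classify": {"n_trees": 500, "mtry": 5, "bootstrap_fraction": 0.63},
    "keyhab": {"t_psi": None, "include": ["excellent"]},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


@dataclass
class Manifest:
    path: Path
    entries: list[dict] = field(default_factory=list)

    def add(self, stage: str, artifact: Path) -> None:
        digest = hashlib.sha256(artifact.read_bytes()).hexdigest()
        self.entries.append({"stage": stage,
                             "path": str(artifact.relative_to(self.path.parent)),
                             "sha256": digest})
        self.write()

    def write(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.entries, fh, indent=2)


@dataclass
class PipelineState:
    """In-memory results shared between stages."""

    config: dict
    out_dir: Path
    manifest: Manifest
    landscape: synth.Landscape | None = None
    presences: occ.PresenceSet | None = None
    design: synth.GroundTruthDesign | None = None
    evi_series: list | None = None
    study_mask: BinaryMask | None = None
    fine_study_mask: BinaryMask | None = None
    threshold: occ.ThresholdSelection | None = None
    psi_surface: GridLayer | None = None
    phenologies: pd.DataFrame | None = None
    changepoints: list | None = None
    forest: classify.OrdinalForestModel | None = None
    category_surface: GridLayer | None = None
    index_surface: classify.SuitabilityIndexSurface | None = None
    report: keyhab.KeyHabitatReport | None = None


def _save_grid(state: PipelineState, stage: str, name: str,
               layer: GridLayer | BinaryMask) -> None:
    path = state.out_dir / f"{name}.asc"
    write_ascii_grid(layer, path)
    state.manifest.add(stage, path)


def _save_text(state: PipelineState, stage: str, name: str,
               text: str) -> None:
    path = state.out_dir / name
    path.write_text(text)
    state.manifest.add(stage, path)


# ---------------------------------------------------------------------------
# stages

def stage_synth(state: PipelineState) -> None:
    cfg, seed = state.config["synth"], state.config["seed"]
    land = synth.generate_landscape(
        seed, tuple(cfg["coarse_shape"]), cfg["refine_factor"],
        layer_specs={n: synth.KNOWN_LAYERS[n] for n in cfg["layers"]})
    state.landscape = land
    state.presences = synth.simulate_presences(
        land, cfg["n_presences"], seed=seed + 1)
    state.design = synth.simulate_ground_truth(
        land, cfg["n_points"], cfg["stops"], cfg["spacing_m"],
        cfg["n_discard"], seed=seed + 2, label_noise=cfg["label_noise"])
    state.evi_series = synth.simulate_evi(
        state.design, cfg["evi_start"], cfg["evi_end"], seed=seed + 3)

    for name, layer in land.layers.items():
        _save_grid(state, "synth", f"coarse_{name}", layer)
    for name, layer in land.fine_layers.items():
        _save_grid(state, "synth", f"fine_{name}", layer)
    _save_text(state, "synth", "presences.csv",
               state.presences.to_frame().to_csv(index=False))
    _save_text(state, "synth", "design.json", state.design.to_json())
    evi_df = pd.concat([s.to_frame() for s in state.evi_series])
    _save_text(state, "synth", "evi_series.csv", evi_df.to_csv(index=False))


def stage_studyarea(state: PipelineState) -> None:
    cfg = state.config["studyarea"]
    bounds = {"ELEV": tuple(cfg["elev"]), "TREE": tuple(cfg["tree"]),
              "AI": tuple(cfg["ai"])}
    land = state.landscape
    state.study_mask = studyarea.delineate_study_area(land.layers, bounds)
    fine_masks = [studyarea.binarize(land.fine_layers[n], lo, hi)
                  for n, (lo, hi) in bounds.items()]
    state.fine_study_mask = studyarea.intersect(fine_masks)
    if state.study_mask.area_km2 == 0:
        raise ValueError("study area is empty; adjust studyarea bounds")
    _save_grid(state, "studyarea", "study_mask", state.study_mask)
    _save_grid(state, "studyarea", "fine_study_mask", state.fine_study_mask)


def stage_occurrence(state: PipelineState) -> None:
    cfg, seed = state.config["occurrence"], state.config["seed"]
    land, mask = state.landscape, state.study_mask

    # keep only records inside the study area (mirrors the record screening
    # that precedes model fitting)
    grid = land.coarse_grid
    row, col = grid.cell_of(state.presences.x, state.presences.y)
    inside = mask.as_bool()[np.clip(row, 0, grid.shape[0] - 1),
                            np.clip(col, 0, grid.shape[1] - 1)]
    records = state.presences.subset(np.flatnonzero(inside))
    if len(records) < cfg["min_records"]:
        raise ValueError(
            f"only {len(records)} presence records fall inside the study "
            f"area (need >= {cfg['min_records']})")

    all_names = sorted({n for f in cfg["formulas"].values() for n in f})
    stack = occ.CovariateStack(all_names,
                               {n: land.layers[n] for n in all_names},
                               study_mask=mask)
    stack = occ.transform_and_standardize(stack, cfg["skewed"])

    splits = occ.partition_records(records, cfg["frac"],
                                   cfg["n_replicates"], seed=seed + 10)
    fits = {name: [occ.fit_maxlike(s.calibration, stack, formula,
                                   replicate_id=s.replicate_id)
                   for s in splits]
            for name, formula in cfg["formulas"].items()}
    best = occ.select_best_model(fits)

    outside = BinaryMask((mask.values == 0).astype(np.uint8),
                         mask.cell_size, mask.origin)
    pseudo = occ.generate_pseudoabsences(outside, cfg["n_pseudoabsences"],
                                         seed=seed + 11)
    eval_stack = occ.CovariateStack(all_names, dict(stack.layers),
                                    study_mask=None,
                                    transforms=dict(stack.transforms),
                                    standardization=dict(stack.standardization))
    metrics = [occ.evaluate_fit(fit, split.validation, pseudo, eval_stack)
               for fit, split in zip(fits[best], splits)]
    chosen = occ.rank_replicates(metrics)[:cfg["n_selected"]]
    state.threshold = occ.select_threshold(metrics, chosen)

    fine_stack = occ.apply_training_state(
        {n: land.fine_layers[n] for n in all_names}, stack,
        study_mask=state.fine_study_mask)
    chosen_fits = [f for f in fits[best] if f.replicate_id in chosen]
    surfaces = [occ.predict_surface(f, fine_stack) for f in chosen_fits]
    mean_vals = np.mean([s.values for s in surfaces], axis=0)
    nod = surfaces[0].mask
    mean_vals[~nod] = surfaces[0].nodata
    state.psi_surface = surfaces[0].with_values(mean_vals)

    payload = {
        "n_records": len(records),
        "best_model": best,
        "fits": {name: [{"replicate": f.replicate_id, "aicc": f.aicc,
                         "loglik": f.loglik, "converged": bool(f.converged),
                         "beta": list(map(float, f.beta))}
                        for f in reps]
                 for name, reps in fits.items()},
        "metrics": [{"replicate": m.replicate_id, "auc": m.auc,
                     "cor": m.cor, "maxSSS_threshold": m.maxsss_threshold,
                     "max_kappa": m.max_kappa} for m in metrics],
        "selected_replicates": list(state.threshold.selected_replicates),
        "t_psi": state.threshold.t_psi,
    }
    _save_text(state, "occurrence", "occurrence.json",
               json.dumps(payload, indent=2))
    _save_grid(state, "occurrence", "psi_surface", state.psi_surface)


def stage_evi(state: PipelineState) -> None:
    cfg = state.config["evi"]
    filtered = [evi.filter_by_qa(s) for s in state.evi_series]
    cps = [evi.detect_changepoint(s, cfg["min_seg"], cfg["penalty"])
           for s in filtered]
    phen = [evi.phenology(s, cp) for s, cp in zip(filtered, cps)]
    state.changepoints = cps
    state.phenologies = evi.phenology_matrix(phen)
    summary = evi.summarize_degradation(cps, state.design.labels.loc[
        state.phenologies.index].tolist())

    cp_payload = [{"location_id": c.location_id, "tau": c.tau,
                   "prior_mean": c.prior_mean, "current_mean": c.current_mean,
                   "prior_var": c.prior_var, "current_var": c.current_var,
                   "statistic": c.test_statistic,
                   "significant": bool(c.significant)} for c in cps]
    _save_text(state, "evi", "changepoints.json",
               json.dumps(cp_payload, indent=2))
    _save_text(state, "evi", "phenology.csv",
               state.phenologies.to_csv(index_label="location_id"))
    _save_text(state, "evi", "degradation.json", json.dumps({
        "pct_reduced": summary.pct_reduced,
        "chi2": summary.chi2, "df": summary.df, "p_value": summary.p_value,
    }, indent=2))


def stage_classify(state: PipelineState) -> None:
    cfg, seed = state.config["classify"], state.config["seed"]
    X = state.phenologies.to_numpy()
    # guard the rare case of a phenology period with no post-change data
    if np.isnan(X).any():
        col_med = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), col_med, X)
    labels = state.design.labels.loc[state.phenologies.index]
    params = classify.ForestParams(cfg["n_trees"], cfg["mtry"],
                                   cfg["bootstrap_fraction"])
    state.forest = classify.fit_forest(X, labels, params, seed=seed + 20)
    corrected = classify.weighted_oob(state.forest.oob_confusion)

    layers = synth.simulate_evi_layers(state.landscape, seed=seed + 21)
    cat, idx = classify.predict_surface(state.forest, layers)
    # restrict predictions to the fine study area
    fine_mask = state.fine_study_mask.as_bool()
    for lyr in (cat, idx.layer):
        lyr.values[~fine_mask] = lyr.nodata
    state.category_surface, state.index_surface = cat, idx

    _save_text(state, "classify", "classification.json", json.dumps({
        "n_trees": params.n_trees,
        "oob_confusion": state.forest.oob_confusion.tolist(),
        "raw_error": corrected.raw_error,
        "weighted_error": corrected.weighted_error,
    }, indent=2))
    _save_grid(state, "classify", "category_surface", cat)
    _save_grid(state, "classify", "suitability_index", idx.layer)


def stage_keyhab(state: PipelineState) -> None:
    cfg = state.config["keyhab"]
    t_psi = cfg["t_psi"]
    if t_psi is None:
        t_psi = state.threshold.t_psi
    overlap = keyhab.overlap_index(state.psi_surface, state.index_surface)
    report, key, expanded = keyhab.build_report(
        state.psi_surface, state.category_surface, t_psi)
    state.report = report
    _save_grid(state, "keyhab", "overlap_index", overlap)
    _save_grid(state, "keyhab", "key_habitat", key)
    _save_grid(state, "keyhab", "key_habitat_expanded", expanded)
    included = set(cfg.get("include") or ["excellent"])
    if included != {"excellent"}:
        selected = keyhab.delineate_key(state.psi_surface,
                                        state.category_surface, t_psi,
                                        included)
        _save_grid(state, "keyhab", "key_habitat_selected", selected)
    _save_text(state, "keyhab", "report.json", report.to_json())


_STAGE_FUNCS = {
    "synth": stage_synth,
    "studyarea": stage_studyarea,
    "occurrence": stage_occurrence,
    "evi": stage_evi,
    "classify": stage_classify,
    "keyhab": stage_keyhab,
}


def run_pipeline(config: dict | str | Path,
                 upto: str | None = None) -> PipelineState:
    """Execute the stages in dependency order (optionally stopping after
    ``upto``); returns the in-memory state; writes artifacts + manifest."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else \
        load_config(None, config)
    if upto is not None and upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    state = PipelineState(cfg, out_dir, Manifest(out_dir / "manifest.json"))
    for stage in STAGES:
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](state)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        if stage == upto:
            break
    return state
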