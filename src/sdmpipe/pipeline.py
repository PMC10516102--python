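"""End-to-end orchestration: simulate → model → project → assess.

`run_pipeline` executes the whole analysis on a simulated landscape:
climate simulation and scenario futures, PCA reduction, occurrence
thinning and pseudo-absence generation, spatially structured
cross-validation, the five-algorithm ensemble, max-Jaccard
binarization, land-cover masking, range-change and richness
accounting, and the two protected-area assessments. Every stochastic
stage derives its seed deterministically from the master seed, so a
rerun with the same config reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .climate_space import ClimatePCA
from .evaluation import (
    EvaluationRecord,
    auc,
    build_ensemble,
    binarize,
    confusion,
    jaccard,
    max_jaccard_threshold,
)
from .occurrences import (
    PRESENCE,
    PSEUDO_ABSENCE,
    LabeledPoints,
    extract_env,
    fit_envelope,
    sample_pseudo_absences,
    thin,
)
from .partitioning import assign_folds
from .protected_areas import (
    filter_pas,
    gap_analysis,
    null_model_test,
    protected_richness_proportion,
)
from .range_dynamics import (
    mask_landcover,
    range_area,
    range_change,
    stack_richness,
    suitability_change,
)
from .raster import ClimateStack, RasterGrid, write_ascii_grid
from .sdm import ALGORITHMS, SDMClassifier
from .synthetic import (
    LANDCOVER_ALLOWED,
    LANDCOVER_CLASSES,
    ScenarioShift,
    SyntheticConfig,
    VirtualSpecies,
)

__all__ = ["RunConfig", "SpeciesModelResult", "model_species", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the analysis constants fixed at
    their standard values (95% variance, 15-record rule, k=3, 1:1
    pseudo-absences, 5% stability, 50 km² PA filter, 999 replicates,
    alpha 0.05)."""

    # synthetic landscape
    grid_rows: int = 60
    grid_cols: int = 60
    cell_area: float = 100.0
    n_climate_vars: int = 19
    spatial_range: float = 10.0
    # virtual species
    n_species: int = 3
    n_presences: int = 200
    # scenarios
    scenarios: tuple[str, ...] = ("rcp45", "rcp85")
    n_gcms: int = 5
    # analysis constants
    variance_threshold: float = 0.95
    thinning_factor: float = 2.0
    pa_ratio: float = 1.0
    min_records_checkerboard: int = 15
    k_folds: int = 3
    algorithms: tuple[str, ...] = ALGORITHMS
    stability_pct: float = 5.0
    pa_min_area_km2: float = 50.0
    null_reps: int = 999
    alpha: float = 0.05
    # protected areas
    n_pas: int = 30
    pa_size_min: int = 2
    pa_size_max: int = 30
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return (self.master_seed * 7919 + zlib.crc32(stage.encode())) % (2**31)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenarios"] = list(self.scenarios)
        d["algorithms"] = list(self.algorithms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("scenarios", "algorithms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SpeciesModelResult:
    """Everything the downstream accounting needs for one species."""

    species_id: str
    points: LabeledPoints
    evaluations: list[EvaluationRecord]
    member_ids: list[str]
    threshold: float
    ensemble_jaccard: float
    suitability: dict[str, RasterGrid]  # scenario -> continuous ensemble map
    binary: dict[str, RasterGrid]  # scenario -> thresholded map (pre-landcover)


def _candidate_blocks(config: RunConfig) -> np.ndarray:
    cell = float(np.sqrt(config.cell_area))
    extent = max(config.grid_rows, config.grid_cols) * cell
    lo = config.thinning_factor * cell
    hi = max(extent / 2.0, lo * 2.0)
    return np.geomspace(lo, hi, num=8)


def _fold_pairs(folds: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) with each fold serving once as test."""
    pairs = []
    for f in np.unique(folds):
        pairs.append((np.nonzero(folds != f)[0], np.nonzero(folds == f)[0]))
    return pairs


def _background_points(
    presences: LabeledPoints, stack: ClimateStack, n: int, seed: int
) -> LabeledPoints:
    """Uniform background draws from the study area (for the MaxEnt-like
    presence-background algorithm)."""
    X, rows, cols = stack.to_table()
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=min(n, rows.size), replace=False)
    x, y = stack.grid.xy_of(rows[pick], cols[pick])
    return LabeledPoints(
        species_id=presences.species_id,
        coords=np.column_stack([x, y]),
        labels=np.full(pick.size, PSEUDO_ABSENCE, dtype=int),
        env=pd.DataFrame(X[pick], columns=stack.names),
    )


def model_species(
    points: LabeledPoints,
    present_scores: ClimateStack,
    future_scores: dict[str, list[ClimateStack]],
    config: RunConfig,
    seed: int,
) -> SpeciesModelResult:
    """Fit the five algorithms with cross-validation, ensemble, threshold.

    `points` must carry presence/pseudo-absence labels, env values and
    fold labels. `future_scores` maps a scenario id to its per-GCM score
    stacks; the scenario's continuous map is the mean over GCMs of the
    ensemble map, binarized with the present-day threshold.
    """
    folds = points.folds
    if folds is None:
        raise ValueError("points must carry fold labels")
    evaluations: list[EvaluationRecord] = []
    fold_fits: dict[str, list[SDMClassifier]] = {a: [] for a in config.algorithms}
    fold_jaccards: dict[str, list[float]] = {a: [] for a in config.algorithms}

    for fold_id, (train_idx, test_idx) in enumerate(_fold_pairs(folds)):
        train = points.subset(train_idx)
        test = points.subset(test_idx)
        if len(np.unique(test.labels)) < 2 or len(np.unique(train.labels)) < 2:
            continue
        for alg in config.algorithms:
            if alg == "maxent_like":
                pres = train.presences()
                bg = _background_points(
                    pres, present_scores, pres.n, seed + 13 * fold_id
                )
                fit_data = LabeledPoints.concat([pres, bg])
            else:
                fit_data = train
            model = SDMClassifier(algorithm=alg, seed=seed).fit(
                fit_data.env, fit_data.labels
            )
            fold_fits[alg].append(model)
            scores = model.predict_suitability(test.env)
            thr, jac = max_jaccard_threshold(scores, test.labels)
            evaluations.append(
                EvaluationRecord(
                    species_id=points.species_id,
                    algorithm_id=alg,
                    fold=fold_id,
                    jaccard=jac,
                    auc=auc(scores, test.labels),
                    threshold=thr,
                )
            )
            fold_jaccards[alg].append(jac)

    scores_by_alg = {a: float(np.mean(js)) for a, js in fold_jaccards.items() if js}
    if not scores_by_alg:
        raise ValueError(f"{points.species_id}: no fold produced a two-class evaluation")

    def alg_map(alg: str, stack: ClimateStack) -> RasterGrid:
        maps = [m.predict_map(stack) for m in fold_fits[alg]]
        return maps[0].with_values(np.mean([m.values for m in maps], axis=0))

    present_maps = {a: alg_map(a, present_scores) for a in scores_by_alg}
    ens = build_ensemble(
        present_maps, scores_by_alg, species_id=points.species_id, scenario_id="present"
    )

    # species threshold: max-Jaccard of ensemble suitability at the
    # occurrence/pseudo-absence points (each point was a test point once)
    pt_scores = ens.map.values[tuple(present_scores.grid.cell_of(points.x, points.y))]
    threshold, ens_jac = max_jaccard_threshold(pt_scores, points.labels)

    suitability = {"present": ens.map}
    binary = {"present": binarize(ens.map, threshold)}
    for scen, stacks in future_scores.items():
        gcm_maps = []
        for st in stacks:
            member_maps = [alg_map(a, st).values for a in ens.member_ids]
            gcm_maps.append(np.mean(member_maps, axis=0))
        scen_map = present_scores.grid.with_values(np.mean(gcm_maps, axis=0))
        suitability[scen] = scen_map
        binary[scen] = binarize(scen_map, threshold)

    return SpeciesModelResult(
        species_id=points.species_id,
        points=points,
        evaluations=evaluations,
        member_ids=ens.member_ids,
        threshold=threshold,
        ensemble_jaccard=ens_jac,
        suitability=suitability,
        binary=binary,
    )


def _default_virtual_species(config: RunConfig, names: list[str]) -> list[VirtualSpecies]:
    """Seeded virtual species: 2-variable Gaussian niches with modest
    optima offsets and breadth 0.4 sd.

    One niche variable is drawn from the temperature block (first 11
    layers) and one from the precipitation block, so niches span two
    distinct climate gradients rather than two copies of one.
    """
    rng = np.random.default_rng(config.stage_seed("species"))
    n_temp = min(11, max(1, len(names) - 1))
    out = []
    for i in range(config.n_species):
        vars_ = (
            str(rng.choice(names[:n_temp])),
            str(rng.choice(names[n_temp:])) if names[n_temp:] else str(rng.choice(names)),
        )
        optima = tuple(rng.uniform(-0.6, 0.6, size=2).round(3))
        out.append(
            VirtualSpecies(
                species_id=f"vsp{i + 1:02d}",
                niche_vars=vars_,
                optima=optima,
                breadths=(0.4, 0.4),
            )
        )
    return out


def prepare_species_points(
    true_suit: RasterGrid,
    present_scores: ClimateStack,
    config: RunConfig,
    seed: int,
    species_id: str = "vsp",
) -> LabeledPoints:
    """Sample → thin → extract env → envelope → pseudo-absences → folds."""
    cell = float(np.sqrt(config.cell_area))
    pres = synthetic.sample_presences(
        true_suit, config.n_presences, seed=seed, species_id=species_id
    )
    pres = thin(pres, cell_size=config.thinning_factor * cell, seed=seed + 1)
    pres = extract_env(pres, present_scores)
    env_envelope = fit_envelope(pres)
    absences = sample_pseudo_absences(
        pres, present_scores, env_envelope, ratio=config.pa_ratio, seed=seed + 2
    )
    points = LabeledPoints.concat([pres, absences])
    points, _ = assign_folds(
        points,
        candidates=_candidate_blocks(config),
        min_checkerboard=config.min_records_checkerboard,
        k=config.k_folds,
        seed=seed + 3,
    )
    return points


def _mean_stack(stacks: list[ClimateStack], scenario: str) -> ClimateStack:
    names = stacks[0].names
    layers = {
        n: stacks[0][n].with_values(np.mean([s[n].values for s in stacks], axis=0))
        for n in names
    }
    return ClimateStack(layers, scenario=scenario)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full synthetic analysis; write tables, rasters, manifest.

    Returns a dict with the in-memory results and the manifest.
    """
    outdir = Path(outdir)
    (outdir / "rasters").mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------
    syn = SyntheticConfig(
        grid_rows=config.grid_rows,
        grid_cols=config.grid_cols,
        cell_area=config.cell_area,
        n_climate_vars=config.n_climate_vars,
        spatial_range=config.spatial_range,
        seed=config.stage_seed("climate"),
    )
    present = synthetic.generate_climate(syn)
    names = present.names
    shifts = [
        s
        for s in synthetic.default_scenario_shifts(names, n_gcms=config.n_gcms)
        if s.scenario_id in config.scenarios
    ]
    futures: dict[str, list[ClimateStack]] = {s: [] for s in config.scenarios}
    for shift in shifts:
        futures[shift.scenario_id].append(synthetic.generate_future(present, shift))

    study_mask = np.ones((config.grid_rows, config.grid_cols), dtype=bool)

    # --- pca ----------------------------------------------------------
    pca = ClimatePCA(variance_threshold=config.variance_threshold).fit(present, study_mask)
    present_scores = pca.transform(present)
    future_scores = {
        scen: [pca.transform(st) for st in stacks] for scen, stacks in futures.items()
    }

    # --- land cover (one model per scenario) --------------------------
    lc_seed = config.stage_seed("landcover")
    landcover = {"present": synthetic.generate_landcover(present, seed=lc_seed)}
    for scen, stacks in futures.items():
        landcover[scen] = synthetic.generate_landcover(
            _mean_stack(stacks, scen), seed=lc_seed
        )
    allowed_codes = [LANDCOVER_CLASSES.index(c) for c in LANDCOVER_ALLOWED]

    # --- species models -----------------------------------------------
    species = _default_virtual_species(config, names)
    results: list[SpeciesModelResult] = []
    masked: dict[str, dict[str, RasterGrid]] = {}
    change_rows = []
    for i, vs in enumerate(species):
        seed = config.stage_seed(f"species:{vs.species_id}")
        true_suit = synthetic.make_virtual_species(present, vs)
        points = prepare_species_points(
            true_suit, present_scores, config, seed, species_id=vs.species_id
        )
        res = model_species(points, present_scores, future_scores, config, seed)
        results.append(res)
        masked[vs.species_id] = {
            scen: mask_landcover(res.binary[scen], landcover[scen], allowed_codes)
            for scen in res.binary
        }
        area_present = range_area(masked[vs.species_id]["present"], config.cell_area)
        for scen in config.scenarios:
            area_future = range_area(masked[vs.species_id][scen], config.cell_area)
            rec = range_change(
                area_present,
                area_future,
                species_id=vs.species_id,
                scenario_id=scen,
                stability_pct=config.stability_pct,
            )
            rec.suitability_change_pct = suitability_change(
                res.suitability["present"], res.suitability[scen], study_mask
            )
            change_rows.append(rec)

    # --- richness ------------------------------------------------------
    scenarios_all = ["present", *config.scenarios]
    richness = {
        scen: stack_richness([masked[vs.species_id][scen] for vs in species])
        for scen in scenarios_all
    }

    # --- protected areas -----------------------------------------------
    mask_grid = present.grid.with_values(study_mask.astype(float))
    pas_raw = synthetic.generate_protected_areas(
        mask_grid,
        config.n_pas,
        (config.pa_size_min, config.pa_size_max),
        seed=config.stage_seed("pas"),
        cell_area=config.cell_area,
    )
    pas = filter_pas(pas_raw, study_mask, config.cell_area, min_area=config.pa_min_area_km2)

    gap_rows = [
        gap_analysis(
            masked[vs.species_id][scen],
            pas,
            config.cell_area,
            species_id=vs.species_id,
            scenario_id=scen,
        )
        for vs in species
        for scen in scenarios_all
        if range_area(masked[vs.species_id][scen], config.cell_area) > 0
    ]

    null_rows = []
    rng = np.random.default_rng(config.stage_seed("nullmodel"))
    for scen in scenarios_all:
        for pa in pas:
            r = null_model_test(
                pa,
                richness[scen],
                study_mask,
                n=config.null_reps,
                alpha=config.alpha,
                rng=rng,
            )
            null_rows.append(
                {
                    "scenario": scen,
                    "pa_id": pa.pa_id,
                    "category": pa.category,
                    "observed": r.observed_stat,
                    "null_mean": float(r.null_stats.mean()),
                    "p_value": r.p_value,
                    "effective": r.effective,
                }
            )

    prop_rows = [
        {
            "scenario": scen,
            "protected_richness_pct": protected_richness_proportion(
                richness[scen], pas, study_mask
            ),
        }
        for scen in scenarios_all
    ]

    # --- write outputs -------------------------------------------------
    float_fmt = "%.10g"
    eval_df = pd.DataFrame(
        [
            {
                "species": e.species_id,
                "algorithm": e.algorithm_id,
                "fold": e.fold,
                "jaccard": e.jaccard,
                "auc": e.auc,
                "threshold": e.threshold,
            }
            for res in results
            for e in res.evaluations
        ]
    )
    change_df = pd.DataFrame(
        [
            {
                "species": r.species_id,
                "scenario": r.scenario_id,
                "area_present_km2": r.area_present,
                "area_future_km2": r.area_future,
                "pct_change": r.pct_change,
                "change_class": r.change_class,
                "suitability_change_pct": r.suitability_change_pct,
            }
            for r in change_rows
        ]
    )
    gap_df = pd.DataFrame(
        [
            {
                "species": g.species_id,
                "scenario": g.scenario_id,
                "range_area_km2": g.range_area,
                "target_pct": g.target_pct,
                "achieved_pct": g.achieved_pct,
                "attainment_pct": g.attainment,
                "category": g.category,
            }
            for g in gap_rows
        ]
    )
    null_df = pd.DataFrame(null_rows)
    prop_df = pd.DataFrame(prop_rows)
    pa_df = pd.DataFrame(
        [{"pa_id": p.pa_id, "category": p.category, "area_km2": p.area} for p in pas]
    )

    tables = {
        "evaluations.csv": eval_df,
        "range_change.csv": change_df,
        "gap_analysis.csv": gap_df,
        "null_model.csv": null_df,
        "protected_richness.csv": prop_df,
        "pa_units.csv": pa_df,
    }
    for fname, df in tables.items():
        df.to_csv(outdir / fname, index=False, float_format=float_fmt)
    pca.to_json(outdir / "pca.json")
    for scen, grid in richness.items():
        write_ascii_grid(grid, outdir / "rasters" / f"richness_{scen}.asc")
    for vs in species:
        for scen, grid in masked[vs.species_id].items():
            write_ascii_grid(
                grid, outdir / "rasters" / f"range_{vs.species_id}_{scen}.asc"
            )

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": {
            s: config.stage_seed(s) for s in ("climate", "landcover", "species", "pas", "nullmodel")
        },
        "n_axes": pca.n_axes_,
        "files": {},
    }
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return {
        "config": config,
        "pca": pca,
        "species": species,
        "results": results,
        "masked": masked,
        "richness": richness,
        "pas": pas,
        "tables": tables,
        "manifest": manifest,
    }
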