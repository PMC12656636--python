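"""End-to-end orchestration of the habitat-mapping blueprint.

``run_blueprint`` chains every stage — simulate island, derive terrain
predictors, clean and consolidate surveys, prune collinearity, select
the feature x RM configuration, validate under LOCO, build decision
products, run the sensitivity sweeps and rank survey segments — under a
single global seed.  Each stochastic stage consumes a seed derived
deterministically from the global one (hash of seed + stage name), so
stages stay decoupled and the whole run is reproducible bit for bit.

Outputs land in a run directory together with a machine-readable
manifest listing every artifact with its SHA-256 hash and the stage
seeds.  With ``public_mode`` enabled, coordinate-bearing exports
(occurrence records, presence sites, suitability and CORE rasters,
shoreline and segment geometries) are suppressed and only de-identified
aggregates and reports are written, mirroring the data policy for
endangered-species localities.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import decision, maxent, occurrence, terrain, validation
from .grids import Raster, write_ascii_grid
from .island import (
    IslandConfig,
    TruthParams,
    generate_dem,
    shoreline_from_dem,
    simulate_surveys,
    truth_suitability,
)

__all__ = ["SurveyConfig", "RunConfig", "stage_seed", "run_blueprint"]

log = logging.getLogger("coastcore")

# ecologically prioritized predictors, shielded from collinearity pruning:
# the coast-elevation exposure gradient plus the microsite axes (slope,
# wetness) the species is known to select on
PROTECTED_VARS = ("DIST_COAST_M", "ELEV_M", "SLOPE_DEG", "TWI_APPROX")


@dataclasses.dataclass
class SurveyConfig:
    n_sites: int = 32
    jitter_sd_m: float = 10.0
    duplicate_prob: float = 0.5
    loss_frac: float = 0.2
    detect_prob: float = 0.9


@dataclasses.dataclass
class RunConfig:
    """Full configuration of one blueprint run."""

    island: IslandConfig = dataclasses.field(default_factory=IslandConfig)
    truth: TruthParams = dataclasses.field(default_factory=TruthParams)
    # the demo island is a ~1/6-scale emulation, so the fitting cell scales
    # with it (15 m here vs 90 m on a full-size island)
    terrain: terrain.TerrainConfig = dataclasses.field(
        default_factory=lambda: terrain.TerrainConfig(fit_cell_m=15.0)
    )
    survey: SurveyConfig = dataclasses.field(default_factory=SurveyConfig)
    consolidation_eps_m: float = 30.0
    loco_eps_m: float = 250.0
    cv_folds: int = 5
    classes_grid: tuple[str, ...] = ("l", "lq", "lqh")
    rm_grid: tuple[float, ...] = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)
    hinge_knots: int = 8
    background_target_ratio: float = 25.0
    mask_dist_m: float = 300.0
    belt_q: float = 0.90
    min_cells: int = 3
    belts: tuple[float, ...] = (60.0, 90.0, 120.0)
    mmus: tuple[int, ...] = (1, 3, 5, 9)
    sweep_masks: tuple[float, ...] = (300.0, 450.0, 600.0)
    sweep_ratios: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0)
    segment_len_m: float = 100.0
    segment_window: int = 3
    seed: int = 42
    public_mode: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["island"] = IslandConfig(**raw["island"])
        raw["truth"] = TruthParams(**raw["truth"])
        raw["terrain"] = terrain.TerrainConfig(**raw["terrain"])
        raw["survey"] = SurveyConfig(**raw["survey"])
        for key in ("classes_grid", "rm_grid", "belts", "mmus", "sweep_masks", "sweep_ratios"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of the global seed + stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    """Bookkeeping for one run directory: writes, hashes, timings."""

    def __init__(self, out_dir: Path, public_mode: bool):
        self.dir = out_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        self.public_mode = public_mode
        self.files: dict[str, str] = {}
        self.suppressed: list[str] = []
        self.stages: list[dict] = []

    def emit(self, name: str, writer, sensitive: bool = False) -> None:
        if sensitive and self.public_mode:
            self.suppressed.append(name)
            return
        path = self.dir / name
        writer(path)
        self.files[name] = _sha256(path)

    def stage(self, name: str, t0: float, **params) -> None:
        entry = {"stage": name, "seconds": round(time.time() - t0, 3), **params}
        self.stages.append(entry)
        log.info("stage=%s %s", name, params)


@dataclasses.dataclass
class DesignData:
    """Everything the modeling stages need, prepared reproducibly."""

    dem: Raster
    shoreline: object
    stack: terrain.PredictorStack
    truth: Raster
    table: pd.DataFrame
    labeled: pd.DataFrame
    fit_stack: terrain.PredictorStack
    map_stack: terrain.PredictorStack
    dist_map: Raster
    site_xy: np.ndarray
    pres_rows: np.ndarray
    background: maxent.BackgroundSample
    bg_rows: np.ndarray
    retained: list


def build_design(config: RunConfig) -> DesignData:
    """Simulate the island and prepare the model design matrices.

    Runs the generator, labels and consolidates the survey records,
    extracts fit-scale predictor rows at the recent (P3-P4) presence
    sites, samples the accessible background, and prunes collinear
    variables.  Deterministic given ``config.seed``.
    """
    island_cfg = dataclasses.replace(config.island, seed=stage_seed(config.seed, "island"))
    truth_params = dataclasses.replace(
        config.truth, noise_seed=stage_seed(config.seed, "truthnoise")
    )
    dem = generate_dem(island_cfg)
    shoreline, _land = shoreline_from_dem(dem)
    stack = terrain.derive_predictors(dem, config.terrain)
    truth = truth_suitability(stack, truth_params)
    table = simulate_surveys(
        truth,
        island_cfg,
        n_sites=config.survey.n_sites,
        seed=stage_seed(config.seed, "survey"),
        jitter_sd_m=config.survey.jitter_sd_m,
        duplicate_prob=config.survey.duplicate_prob,
        loss_frac=config.survey.loss_frac,
        detect_prob=config.survey.detect_prob,
    )
    labeled, _errors = occurrence.assign_periods(table)
    recent = labeled[labeled["presence"] & labeled["period"].isin(["P3", "P4"])]
    labels = occurrence.consolidate_sites(
        recent[["x", "y"]].to_numpy(), config.consolidation_eps_m
    )
    site_xy = occurrence.site_representatives(recent[["x", "y"]].to_numpy(), labels)
    fit_stack, map_stack = terrain.scale_transfer(
        stack, config.terrain.fit_cell_m, config.terrain.map_cell_m
    )
    rows_all = fit_stack.extract_at_xy(site_xy[:, 0], site_xy[:, 1])
    on_land = np.isfinite(rows_all).all(axis=1)
    site_xy = site_xy[on_land]
    dist_map = stack["DIST_COAST_M"]
    mask = maxent.accessible_mask(dist_map.data, config.mask_dist_m, stack.valid_mask())
    background = maxent.sample_background(
        mask,
        fit_stack,
        list(terrain.CANONICAL_LAYERS),
        n_presence=len(site_xy),
        target_ratio=config.background_target_ratio,
        seed=stage_seed(config.seed, "background"),
        mask_grid=dist_map,
    )
    retained = maxent.spearman_prune(
        background.rows, list(terrain.CANONICAL_LAYERS), protected=PROTECTED_VARS
    )
    idx = [list(terrain.CANONICAL_LAYERS).index(n) for n in retained]
    retained = maxent.vif_prune(background.rows[:, idx], retained, protected=PROTECTED_VARS)
    pres_rows = fit_stack.extract_at_xy(site_xy[:, 0], site_xy[:, 1], retained)
    bg_rows = fit_stack.extract_at_xy(background.xy[:, 0], background.xy[:, 1], retained)
    return DesignData(
        dem=dem, shoreline=shoreline, stack=stack, truth=truth, table=table,
        labeled=labeled, fit_stack=fit_stack, map_stack=map_stack,
        dist_map=dist_map, site_xy=site_xy, pres_rows=pres_rows,
        background=background, bg_rows=bg_rows, retained=retained,
    )


def run_blueprint(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full blueprint; returns the manifest (also written)."""
    run = _Run(Path(out_dir), config.public_mode)
    manifest: dict = {"seed": config.seed, "public_mode": config.public_mode}

    # --- simulate + design --------------------------------------------------
    t0 = time.time()
    design = build_design(config)
    dem, shoreline, stack = design.dem, design.shoreline, design.stack
    truth, table, labeled = design.truth, design.table, design.labeled
    run.emit("dem.asc", lambda p: write_ascii_grid(dem, p))
    run.emit("truth.asc", lambda p: write_ascii_grid(truth, p), sensitive=True)
    run.emit(
        "shoreline.geojson",
        lambda p: Path(p).write_text(shapely.to_geojson(shoreline)),
        sensitive=True,
    )
    run.emit(
        "occurrences.csv",
        lambda p: table.to_csv(p, index=False),
        sensitive=True,
    )
    run.stage("simulate", t0, n_records=len(table),
              seed=stage_seed(config.seed, "survey"))

    # --- occurrence dynamics ------------------------------------------------
    t0 = time.time()
    sites = occurrence.unique_sites_per_period(labeled, config.consolidation_eps_m)
    rates = []
    for _, row in sites.iterrows():
        if row["n_surveyed_sites"] == 0:
            continue
        ci = occurrence.detection_rate_ci(
            int(row["n_presence_sites"]),
            int(row["n_surveyed_sites"]),
            seed=stage_seed(config.seed, f"boot-{row['period']}"),
        )
        rates.append({"period": row["period"], **ci})
    counts = sites.set_index("period")["n_presence_sites"]
    peak = int(counts[["P1", "P2", "P3"]].max())
    recent = int(counts["P4"])
    change_pct = occurrence.percent_change(peak, recent) if peak > 0 else float("nan")
    change = occurrence.grid_change_classify(labeled)
    deid = occurrence.deidentify_export(labeled)
    run.emit("sites_per_period.csv", lambda p: sites.to_csv(p, index=False))
    run.emit("detection_rates.csv", lambda p: pd.DataFrame(rates).to_csv(p, index=False))
    run.emit("grid_change.csv", lambda p: change.to_csv(p, index=False))
    run.emit("deidentified_grid.csv", lambda p: deid.to_csv(p, index=False))
    manifest["occurrence"] = {
        "peak_sites": peak,
        "recent_sites": recent,
        "percent_change": change_pct,
        "change_classes": change["class"].value_counts().to_dict(),
    }
    run.stage("occurrence", t0, peak=peak, recent=recent)

    # --- model design -------------------------------------------------------
    t0 = time.time()
    site_xy, pres_rows = design.site_xy, design.pres_rows
    background, bg_rows, retained = design.background, design.bg_rows, design.retained
    fit_stack, map_stack, dist_map = design.fit_stack, design.map_stack, design.dist_map
    manifest["design"] = {
        "n_presence_sites": int(len(site_xy)),
        "n_background": int(len(bg_rows)),
        "realized_ratio": background.realized_ratio,
        "retained_variables": retained,
    }
    run.stage("design", t0, n_presence=len(site_xy), retained=len(retained))

    # --- model selection ----------------------------------------------------
    t0 = time.time()
    grid_table, chosen = maxent.select_model_grid(
        pres_rows,
        bg_rows,
        retained,
        classes_grid=config.classes_grid,
        rm_grid=config.rm_grid,
        folds=config.cv_folds,
        seed=stage_seed(config.seed, "selection"),
        hinge_knots=config.hinge_knots,
    )
    run.emit("selection_grid.csv", lambda p: grid_table.to_csv(p, index=False))
    manifest["selection"] = {
        "chosen_classes": chosen.feature_classes,
        "chosen_rm": chosen.rm,
    }
    run.stage("selection", t0, classes=chosen.feature_classes, rm=chosen.rm)

    # --- LOCO validation ----------------------------------------------------
    t0 = time.time()
    folds = validation.loco_folds(site_xy, eps_m=config.loco_eps_m)
    pres_cells = np.column_stack(dist_map.xy_to_rowcol(site_xy[:, 0], site_xy[:, 1]))
    bg_cells = np.column_stack([background.cell_rows, background.cell_cols])
    report = validation.evaluate_loco(
        chosen, folds, pres_rows, bg_rows,
        presence_cells=pres_cells, background_cells=bg_cells, var_names=retained,
    )
    run.emit("loco_folds.csv", lambda p: report.per_fold.to_csv(p, index=False))
    manifest["validation"] = report.summary()
    run.stage("loco", t0, **{k: v for k, v in report.summary().items() if k != "scheme"})

    # --- decision products --------------------------------------------------
    t0 = time.time()
    model = maxent.fit_maxent(pres_rows, bg_rows, chosen, retained)
    map_rows, map_cols = np.nonzero(map_stack.subset(retained).valid_mask())
    map_X = map_stack.extract_rows(map_rows, map_cols, retained)
    suit = dem.copy_with(np.full(dem.shape, np.nan))
    suit.data[map_rows, map_cols] = maxent.predict_model(model, map_X, type="cloglog")
    pres_preds = maxent.predict_model(model, pres_rows, type="cloglog")
    bg_preds = maxent.predict_model(model, bg_rows, type="cloglog")

    recent_xy = site_xy  # 2020-2024 consolidated sites drive belt and coverage
    rr, cc = dist_map.xy_to_rowcol(recent_xy[:, 0], recent_xy[:, 1])
    recent_dists = dist_map.data[rr, cc]
    belt, belt_width = decision.coastal_belt(recent_dists, dist_map, q=config.belt_q)

    fold_thetas = report.per_fold.get("youden_theta")
    thresholds = {}
    for rule in decision.THRESHOLD_RULES:
        try:
            thresholds[rule] = decision.compute_threshold(
                rule,
                presence_preds=pres_preds,
                background_preds=bg_preds,
                fold_thresholds=None if fold_thetas is None else fold_thetas.to_numpy(),
                belt_presence_preds=pres_preds[np.isfinite(recent_dists) & (recent_dists <= belt_width)],
            ).value
        except ValueError:
            thresholds[rule] = float("nan")
    theta = thresholds["spec0980"]
    product = decision.core_map(
        suit, theta, belt, min_cells=config.min_cells,
        recent_site_xy=recent_xy, belt_width_m=belt_width,
    )
    run.emit("suitability.asc", lambda p: write_ascii_grid(suit, p), sensitive=True)
    run.emit("core.asc", lambda p: write_ascii_grid(product.core, p), sensitive=True)
    model_json = run.dir / "model.json"
    model.to_json(model_json)
    run.files["model.json"] = _sha256(model_json)
    manifest["decision"] = {
        "thresholds": thresholds,
        "belt_width_m": belt_width,
        "core_area_km2": product.area_km2,
        "coverage": product.coverage,
        "leakage_pre_km2": product.leakage_pre_km2,
        "leakage_post_km2": product.leakage_post_km2,
    }
    run.stage("decide", t0, theta=round(theta, 3), area=round(product.area_km2, 4))

    # --- sensitivity sweeps -------------------------------------------------
    t0 = time.time()
    sweep = decision.mask_ratio_sweep(
        fit_stack, map_stack, pres_rows, dem, dist_map, chosen, retained,
        belt, belt_width, recent_site_xy=recent_xy,
        masks=config.sweep_masks, ratios=config.sweep_ratios,
        min_cells=config.min_cells, seed=stage_seed(config.seed, "sweep"),
    )
    bm = decision.belt_mmu_sweep(
        suit,
        {r: thresholds[r] for r in ("spec0980", "maxtss", "max_ba")
         if np.isfinite(thresholds[r])},
        dist_map, recent_site_xy=recent_xy, belts=config.belts, mmus=config.mmus,
    )
    run.emit("mask_ratio_sweep.csv", lambda p: sweep.table.to_csv(p, index=False))
    run.emit("belt_mmu_sweep.csv", lambda p: bm.to_csv(p, index=False))
    manifest["area_band"] = sweep.band
    run.stage("sweeps", t0, **{k: round(v, 4) for k, v in sweep.band.items()})

    # --- survey segments ----------------------------------------------------
    t0 = time.time()
    segments = decision.segment_rank(
        shoreline, suit, theta, belt,
        segment_len_m=config.segment_len_m, window_segments=config.segment_window,
    )
    run.emit("segments.csv", lambda p: segments.to_csv(p, index=False), sensitive=True)
    run.emit(
        "segment_bands.csv",
        lambda p: segments.groupby("band", dropna=False)
        .size()
        .rename("n_segments")
        .reset_index()
        .to_csv(p, index=False),
    )
    run.stage("segments", t0, n_candidates=int(segments["candidate"].sum()))

    manifest["files"] = run.files
    manifest["suppressed"] = run.suppressed
    manifest["stage_seeds"] = {
        s: stage_seed(config.seed, s)
        for s in ("island", "survey", "background", "selection", "sweep")
    }
    manifest["stages"] = run.stages
    (run.dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
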