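"""Synthetic volcanic-island generator and survey simulator.

Emulates the study system the pipeline targets: a small volcanic island
with a central caldera and high interior, and a near-shore endemic plant
surveyed in four national-survey periods.  The generator provides a DEM,
a shoreline, a known ("truth") suitability surface, and multi-period
occurrence records with the statistical structure the downstream stages
assume — coastal concentration of presences, 20–30 m duplicate clumps,
GPS jitter, and site losses in the most recent period — so that every
stage is testable end-to-end with no external data.

The default truth coefficients are negative for distance-to-coast and
elevation and are calibrated so that the 90th percentile of presence
coastal distances (Q90) lands in the 90 +/- 30 m band, the coastal-belt
scale the decision layer uses.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .grids import Raster

__all__ = [
    "IslandConfig",
    "TruthParams",
    "generate_dem",
    "shoreline_from_dem",
    "truth_suitability",
    "simulate_surveys",
]


@dataclasses.dataclass
class IslandConfig:
    """Geometry and roughness of the synthetic island.

    grid_size cells per side at cell_m resolution; the island is a radial
    cone of height peak_elev_m with an inverted-Gaussian caldera at the
    center (radius caldera_radius_frac of the island radius), radially
    dissected flanks (cliff arcs with cove-like valley notches, floored
    by gentle alluvial aprons) and smoothed Gaussian roughness of sd
    noise_sd_m.  Sea is NoData.  The dissection is what gives the
    coastline its alternating cliff/cove character: suitable near-shore
    habitat ends up alongshore-patchy, as on real volcanic islands.
    """

    grid_size: int = 256
    cell_m: float = 5.0
    peak_elev_m: float = 1000.0
    caldera_radius_frac: float = 0.25
    noise_sd_m: float = 10.0
    # mean-filter window (cells) applied once to the roughness field; sets
    # the correlation length of microtopography (window x cell_m meters)
    noise_smooth_cells: int = 7
    seed: int = 42
    # island radius as a fraction of the grid half-width; leaves a sea ring
    radius_frac: float = 0.9
    # radial ridge-valley dissection of the flanks: amplitude (m) of the
    # angular modulation, growing from the center outward, and the number
    # of ridge-valley pairs around the island
    dissect_amp_m: float = 400.0
    n_ridges: int = 10
    # waveform sharpness: 1 gives sinusoidal ridge-valley relief; larger
    # values narrow the valleys into cove-like notches between cliff arcs
    dissect_sharpness: float = 3.0
    # gentle alluvial ramp (m per m of distance inland) that floors the
    # valley bottoms: deep notches fill to a low-gradient apron instead of
    # cutting below sea level, giving the gravel/talus valley-mouth plains
    # the coastal flora occupies.  The ramp gradient varies smoothly
    # around the island (some valleys flat-floored, others steeper), so
    # elevation and distance-to-coast decouple within the habitat zone
    valley_floor_slope: float = 0.08
    valley_floor_slope_var: float = 0.5  # relative amplitude of the variation

    def __post_init__(self) -> None:
        if self.grid_size < 64:
            raise ValueError("grid_size must be >= 64 to contain an island")
        if self.cell_m <= 0:
            raise ValueError("cell_m must be positive")
        if self.peak_elev_m <= 0:
            raise ValueError("peak_elev_m must be positive")


@dataclasses.dataclass
class TruthParams:
    """Link-scale coefficients of the known suitability surface.

    Suitability = logistic(intercept + beta_coast*DIST_COAST_M
    + beta_elev*ELEV_M - beta_slope_curv*(SLOPE_DEG - slope_opt)^2
    - beta_twi_curv*(TWI_APPROX - twi_opt)^2 + beta_heat*HEAT_LOAD
    + smoothed noise field).

    The two monotone terms are negative by default — suitability falls
    with distance from shore and with elevation, the response signs the
    fitted model must recover; on the dissected island the elevation term
    also excludes the cliff arcs, confining habitat to the cove aprons.
    The optional curvature terms add microsite selectivity (wetness on by
    default; slope off, since 5 m slope is too fine-grained to survive
    GPS jitter), and the smoothed link-noise field stands in for
    unmeasured microhabitat so presences are never perfectly separable
    in predictor space.  Defaults are calibrated so the presence Q90
    coastal distance lands near 90 m.
    """

    beta_coast: float = -0.028  # per m of distance to coast
    beta_elev: float = -0.020  # per m of elevation
    intercept: float = 0.8
    jitter_sd_m: float = 10.0
    slope_opt: float = 40.0  # degrees
    beta_slope_curv: float = 0.0  # per squared degree (off: too fine-grained)
    twi_opt: float = -0.5  # wetness-proxy units in [-2, 0]
    beta_twi_curv: float = 5.0  # per squared wetness unit
    # preference for warm, insolation-exposed flanks: a smooth alongshore
    # gradient (heat load folds aspect about SW) coherent far beyond the
    # GPS-jitter scale
    beta_heat: float = 0.0  # per heat-load unit
    # unmeasured-microhabitat noise: smoothed Gaussian field added to the
    # link, so presences are never perfectly explained by the predictors
    link_noise_sd: float = 0.15
    link_noise_smooth_cells: int = 12
    noise_seed: int = 42

    def __post_init__(self) -> None:
        if self.jitter_sd_m < 0:
            raise ValueError("jitter_sd_m must be >= 0")
        if self.beta_slope_curv < 0 or self.beta_twi_curv < 0:
            raise ValueError("curvature coefficients enter negatively; pass them >= 0")


def generate_dem(config: IslandConfig) -> Raster:
    """Generate the island DEM: cone + caldera + smoothed noise.

    Sea cells (outside the island radius or below sea level) are NoData.
    Only the largest connected landmass is kept, so the result is a single
    island.  Deterministic for a fixed ``config.seed``.
    """
    n = config.grid_size
    cell = config.cell_m
    half = n * cell / 2.0
    radius = config.radius_frac * half
    if radius < 4 * cell:
        raise ValueError("grid too small to contain an island")

    # cell-center coordinates relative to the grid center
    coords = (np.arange(n) + 0.5) * cell - half
    xx, yy = np.meshgrid(coords, coords)
    r = np.hypot(xx, yy)

    elev = config.peak_elev_m * (1.0 - r / radius)
    if config.caldera_radius_frac > 0:
        sigma = config.caldera_radius_frac * radius
        elev -= 0.5 * config.peak_elev_m * np.exp(-((r / sigma) ** 2))
    if config.dissect_amp_m > 0 and config.n_ridges > 0:
        # dissected flanks: radial valleys notched into high coastal arcs,
        # amplitude growing toward the coast.  The waveform 1 - 2*w with
        # w = max(0, cos)^sharpness spends most of the ring near +amp
        # (cliff arcs) with narrow -amp notches (valley coves).
        theta = np.arctan2(yy, xx)
        rng_phase = np.random.default_rng(config.seed).uniform(0, 2 * np.pi)
        w = np.maximum(0.0, np.cos(config.n_ridges * theta + rng_phase))
        w = w**config.dissect_sharpness
        elev += config.dissect_amp_m * (1.0 - 2.0 * w) * (r / radius)

    if config.noise_sd_m > 0:
        rng = np.random.default_rng(config.seed)
        noise = rng.normal(0.0, 1.0, size=(n, n))
        # one mean-filter pass sets the roughness correlation length; the
        # field is rescaled so its sd stays noise_sd_m after smoothing
        noise = ndimage.uniform_filter(noise, size=config.noise_smooth_cells,
                                       mode="nearest")
        elev = elev + noise * (config.noise_sd_m / noise.std())

    if config.valley_floor_slope > 0:
        theta = np.arctan2(yy, xx)
        phase2 = np.random.default_rng(config.seed + 1).uniform(0, 2 * np.pi)
        ramp = config.valley_floor_slope * (
            1.0 + config.valley_floor_slope_var * np.sin(3 * theta + phase2)
        )
        elev = np.maximum(elev, ramp * (radius - r))

    land = (r <= radius) & (elev >= 0.0)
    if not land.any():
        raise ValueError("configuration produced no land")

    # keep the largest connected landmass only
    labels, nlab = ndimage.label(land)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, nlab + 1))
        land = labels == (1 + int(np.argmax(sizes)))

    elev = np.where(land, np.clip(elev, 0.0, config.peak_elev_m), np.nan)
    return Raster(elev, cell_m=cell, origin=(0.0, 0.0))


def shoreline_from_dem(dem: Raster) -> tuple[shapely.Geometry, Raster]:
    """Polygonize the land/NoData interface of a DEM.

    Returns (polygon, land_mask).  The polygon is the union of the land
    cells' squares, so its area equals land-cell count x cell_m^2 exactly;
    every land-cell center lies inside it.
    """
    land = dem.mask
    if not land.any():
        raise ValueError("DEM has no land cells")
    nrow, ncol = dem.shape
    x0, y0 = dem.origin
    rows, cols = np.nonzero(land)
    xmin = x0 + cols * dem.cell_m
    ymin = y0 + (nrow - 1 - rows) * dem.cell_m
    boxes = shapely.box(xmin, ymin, xmin + dem.cell_m, ymin + dem.cell_m)
    polygon = shapely.union_all(boxes)
    mask = dem.copy_with(np.where(land, 1.0, np.nan))
    return polygon, mask


def truth_suitability(predictors, params: TruthParams) -> Raster:
    """Known suitability surface on the logistic link scale.

    ``predictors`` is a PredictorStack (or plain mapping of Raster) that
    must contain DIST_COAST_M and ELEV_M, plus SLOPE_DEG / TWI_APPROX
    when the corresponding curvature coefficients are nonzero.
    """
    try:
        dist = predictors["DIST_COAST_M"]
        elev = predictors["ELEV_M"]
    except KeyError as exc:
        raise KeyError(f"missing predictor required for truth surface: {exc}")
    link = params.intercept + params.beta_coast * dist.data + params.beta_elev * elev.data
    if params.beta_slope_curv > 0:
        try:
            slope = predictors["SLOPE_DEG"]
        except KeyError as exc:
            raise KeyError(f"missing predictor required for truth surface: {exc}")
        link = link - params.beta_slope_curv * (slope.data - params.slope_opt) ** 2
    if params.beta_twi_curv > 0:
        try:
            twi = predictors["TWI_APPROX"]
        except KeyError as exc:
            raise KeyError(f"missing predictor required for truth surface: {exc}")
        link = link - params.beta_twi_curv * (twi.data - params.twi_opt) ** 2
    if params.beta_heat != 0:
        try:
            heat = predictors["HEAT_LOAD"]
        except KeyError as exc:
            raise KeyError(f"missing predictor required for truth surface: {exc}")
        link = link + params.beta_heat * heat.data
    if params.link_noise_sd > 0:
        rng = np.random.default_rng(params.noise_seed)
        field = rng.normal(0.0, 1.0, size=link.shape)
        field = ndimage.uniform_filter(field, size=params.link_noise_smooth_cells,
                                       mode="nearest")
        field *= params.link_noise_sd / field.std()
        link = link + field
    prob = 1.0 / (1.0 + np.exp(-link))
    return dist.copy_with(np.where(np.isfinite(link), prob, np.nan))


def _period_year(period: str, rng: np.random.Generator) -> int:
    years = {
        "P1": [2008],
        "P2": [2014, 2015, 2016],
        "P3": [2020, 2021, 2022],
        "P4": [2023, 2024],
    }
    return int(rng.choice(years.get(period, [2019])))


def simulate_surveys(
    truth: Raster,
    config: IslandConfig,
    n_sites: int = 32,
    periods: Sequence[str] = ("P1", "P2", "P3", "P4"),
    seed: int = 42,
    jitter_sd_m: float = 10.0,
    duplicate_prob: float = 0.5,
    loss_frac: float = 0.2,
    detect_prob: float = 0.9,
    colonize_per_period: int = 1,
    n_patches: int = 0,
    patch_sd_m: float = 100.0,
    patch_min_sep_m: float = 400.0,
    min_site_sep_m: float = 45.0,
) -> pd.DataFrame:
    """Simulate multi-period survey records over a truth surface.

    Site placement is patchy, matching the fragmented distribution of a
    coastal endemic (a continuous core plus scattered satellites rather
    than sites spread evenly alongshore): ``n_patches`` anchor locations
    are drawn proportional to suitability with a minimum mutual
    separation, then site cells are drawn without replacement with
    probability proportional to suitability times a Gaussian kernel
    (sd ``patch_sd_m``) around the nearest anchor, and placed uniformly
    within the cell.  Each period every established site is surveyed: a
    detection (count > 0) with probability ``detect_prob``, else a
    non-detection record (count 0).  A fraction ``loss_frac`` of sites
    disappears in the last period (guaranteed non-detections) to create
    loss cells, and ``colonize_per_period`` new sites appear per period
    after the first to create gains.  Detections emit duplicate records
    offset 15-25 m with probability ``duplicate_prob`` (the 20-30 m clump
    scale consolidation must absorb), and all coordinates get
    N(0, jitter_sd_m^2) GPS noise.

    Returns a DataFrame with columns x, y, crs_epsg, date, count and a
    ``site_true`` index for enumeration oracles in tests.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if len(periods) == 0:
        raise ValueError("periods must be nonempty")
    weights = np.where(truth.mask, truth.data, 0.0).ravel()
    if not np.any(weights > 0):
        raise ValueError("truth surface is all-zero; cannot place sites")

    rng = np.random.default_rng(seed)
    nrow, ncol = truth.shape
    n_land_pos = int(np.count_nonzero(weights > 0))
    n_sites = min(n_sites, n_land_pos)
    p = weights / weights.sum()

    w_site = weights
    if n_patches > 0:
        # optional extra clumping: suitability-weighted anchors with mutual
        # repulsion, sites drawn around them.  With the default dissected
        # island the truth surface is already patchy alongshore, so this
        # is off by default.
        xx, yy = truth.cell_centers()
        fx, fy = xx.ravel(), yy.ravel()
        anchors = []
        for _ in range(200):
            if len(anchors) >= n_patches:
                break
            cand = rng.choice(weights.size, p=p)
            cx, cy = fx[cand], fy[cand]
            if all(np.hypot(cx - ax, cy - ay) >= patch_min_sep_m for ax, ay in anchors):
                anchors.append((cx, cy))
        anchors = np.asarray(anchors)
        d2 = np.min(
            (fx[:, None] - anchors[:, 0]) ** 2 + (fy[:, None] - anchors[:, 1]) ** 2,
            axis=1,
        )
        w_patch = weights * np.exp(-d2 / (2 * patch_sd_m**2))
        if np.count_nonzero(w_patch > 0) >= n_sites:
            w_site = w_patch
    if min_site_sep_m > 0:
        # sites are discrete clumps: sequential suitability-weighted draws
        # with a minimum mutual separation, so distinct sites stay
        # resolvable under the clump-scale consolidation downstream
        xc, yc = truth.cell_centers()
        fxc, fyc = xc.ravel(), yc.ravel()
        p_site = w_site / w_site.sum()
        chosen: list[int] = []
        for _ in range(50 * n_sites):
            if len(chosen) >= n_sites:
                break
            cand = int(rng.choice(weights.size, p=p_site))
            if all(
                np.hypot(fxc[cand] - fxc[c], fyc[cand] - fyc[c]) >= min_site_sep_m
                for c in chosen
            ):
                chosen.append(cand)
        flat_idx = np.array(chosen)
        n_sites = len(flat_idx)
    else:
        flat_idx = rng.choice(weights.size, size=n_sites, replace=False,
                              p=w_site / w_site.sum())
    rows, cols = np.unravel_index(flat_idx, truth.shape)
    x0, y0 = truth.origin
    # uniform position within the chosen cell
    site_x = x0 + (cols + rng.uniform(0, 1, n_sites)) * truth.cell_m
    site_y = y0 + (nrow - 1 - rows + rng.uniform(0, 1, n_sites)) * truth.cell_m

    n_lost = int(round(loss_frac * n_sites))
    lost = set(rng.choice(n_sites, size=n_lost, replace=False).tolist()) if n_lost else set()
    # sites colonizing later periods (gains): absent before their start period
    start_period = np.zeros(n_sites, dtype=int)
    gains = rng.choice(
        [i for i in range(n_sites) if i not in lost],
        size=min(colonize_per_period * (len(periods) - 1), n_sites - n_lost),
        replace=False,
    )
    for j, site in enumerate(gains):
        start_period[site] = 1 + j % (len(periods) - 1)

    records = []
    last = len(periods) - 1
    for pi, period in enumerate(periods):
        for s in range(n_sites):
            if pi < start_period[s]:
                continue
            extinct = s in lost and pi == last
            detected = (not extinct) and (rng.uniform() < detect_prob)
            count = int(1 + rng.poisson(2.0)) if detected else 0
            year = _period_year(period, rng)
            date = f"{year}-{int(rng.integers(5, 10)):02d}-{int(rng.integers(1, 29)):02d}"
            gx = site_x[s] + rng.normal(0, jitter_sd_m)
            gy = site_y[s] + rng.normal(0, jitter_sd_m)
            records.append((gx, gy, truth.crs_epsg, date, count, s))
            if detected and rng.uniform() < duplicate_prob:
                # duplicate detection within the clump scale
                dist = rng.uniform(15.0, 25.0)
                theta = rng.uniform(0, 2 * np.pi)
                records.append(
                    (
                        gx + dist * np.cos(theta),
                        gy + dist * np.sin(theta),
                        truth.crs_epsg,
                        date,
                        max(1, count - 1),
                        s,
                    )
                )
    table = pd.DataFrame(
        records, columns=["x", "y", "crs_epsg", "date", "count", "site_true"]
    )
    return table
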