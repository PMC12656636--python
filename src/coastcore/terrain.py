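"""Terrain and coastal-exposure predictors from a DEM and shoreline.

Derives the twelve predictor layers the habitat model uses, all from a
projected 5 m DEM plus the land/sea interface:

====================  =========================================================
ELEV_M                elevation (m)
SLOPE_DEG             slope (degrees), Horn 8-neighbor stencil
TRI                   terrain ruggedness: RMS elevation difference to neighbors
TPI                   topographic position: elevation minus circular-window mean
EASTNESS, NORTHNESS   sin/cos of aspect (radians clockwise from north)
DIST_COAST_M          Euclidean distance to the shoreline (m)
HEAT_LOAD             McCune-Keon heat-load index (aspect folded about SW)
TWI_APPROX            wetness proxy: -(scaled relief) - (scaled slope)
WAVE_EXP              exp(-distance/decay) x seaward openness over 16 rays
EDGE_SLOPE            mean slope of coast-adjacent cells within the decay radius
CLIFF_NEAR            distance (m) to the nearest cell steeper than a threshold
====================  =========================================================

Conventions that the source data cannot fix are declared here: TRI is the
Riley-style RMS over available 8-neighbors; TPI excludes the focal cell;
the TWI proxy min-max rescales relief and slope island-wide before
summation so the two terms are commensurate; the three exposure metrics
(WAVE_EXP, EDGE_SLOPE, CLIFF_NEAR) are parameterized in
:class:`TerrainConfig` so alternates can be swapped in.

NoData (sea) is never imputed: every windowed statistic uses land cells
only, and all layers are NaN off-island.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Mapping

import numpy as np
from scipy import ndimage, signal

from .grids import Raster

__all__ = [
    "CANONICAL_LAYERS",
    "PredictorStack",
    "TerrainConfig",
    "slope_aspect",
    "tri",
    "tpi",
    "dist_coast",
    "heat_load",
    "twi_proxy",
    "coastal_exposure",
    "derive_predictors",
    "scale_transfer",
]

CANONICAL_LAYERS = (
    "ELEV_M",
    "SLOPE_DEG",
    "TRI",
    "TPI",
    "EASTNESS",
    "NORTHNESS",
    "DIST_COAST_M",
    "HEAT_LOAD",
    "TWI_APPROX",
    "WAVE_EXP",
    "EDGE_SLOPE",
    "CLIFF_NEAR",
)

CLIFF_SENTINEL_M = 1.0e6  # CLIFF_NEAR when no cliff cell exists


@dataclasses.dataclass
class TerrainConfig:
    """Parameters of the derived predictors (all lengths in meters)."""

    tpi_radius_m: float = 90.0
    relief_radius_m: float = 90.0
    latitude_deg: float = 37.5
    exposure_decay_m: float = 200.0
    cliff_slope_deg: float = 40.0
    fit_cell_m: float = 90.0
    map_cell_m: float = 5.0

    def __post_init__(self) -> None:
        if self.tpi_radius_m <= 0 or self.relief_radius_m <= 0:
            raise ValueError("window radii must be positive")
        if not 0 < self.cliff_slope_deg < 90:
            raise ValueError("cliff_slope_deg must be in (0, 90)")
        if not -90 < self.latitude_deg < 90:
            raise ValueError("latitude out of range")


class PredictorStack(Mapping[str, Raster]):
    """Co-registered named raster layers sharing one grid geometry."""

    def __init__(self, layers: Mapping[str, Raster]):
        if not layers:
            raise ValueError("empty stack")
        self._layers = dict(layers)
        first = next(iter(self._layers.values()))
        for name, layer in self._layers.items():
            if not first.same_grid(layer):
                raise ValueError(f"layer {name} is not co-registered")
        self._geom = first

    def __getitem__(self, name: str) -> Raster:
        return self._layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def cell_m(self) -> float:
        return self._geom.cell_m

    @property
    def shape(self) -> tuple[int, int]:
        return self._geom.shape

    @property
    def origin(self) -> tuple[float, float]:
        return self._geom.origin

    def valid_mask(self) -> np.ndarray:
        """Cells finite across *all* layers."""
        mask = np.ones(self.shape, dtype=bool)
        for layer in self._layers.values():
            mask &= layer.mask
        return mask

    def extract_rows(self, rows: np.ndarray, cols: np.ndarray, names=None) -> np.ndarray:
        """Predictor matrix (n_cells x n_layers) at the given cell indices."""
        names = list(names) if names is not None else list(self._layers)
        return np.column_stack([self._layers[n].data[rows, cols] for n in names])

    def extract_at_xy(self, x, y, names=None) -> np.ndarray:
        """Predictor matrix at projected coordinates (nearest-cell lookup).

        Out-of-grid points return NaN rows.  This is how fit-scale
        (aggregated) predictor values are read at point records and at
        background cells sampled on the native grid.
        """
        rows, cols = self._geom.xy_to_rowcol(x, y)
        nrow, ncol = self.shape
        inside = (rows >= 0) & (rows < nrow) & (cols >= 0) & (cols < ncol)
        rows = np.clip(rows, 0, nrow - 1)
        cols = np.clip(cols, 0, ncol - 1)
        out = self.extract_rows(rows, cols, names)
        out[~inside] = np.nan
        return out

    def subset(self, names) -> "PredictorStack":
        return PredictorStack({n: self._layers[n] for n in names})


# ---------------------------------------------------------------------------
# local 3x3 derivatives


def _neighbor_shifts(z: np.ndarray) -> dict[str, np.ndarray]:
    """8-neighbor views via edge-replicated padding; NaN neighbors are kept."""
    zp = np.pad(z, 1, mode="edge")
    return {
        "nw": zp[:-2, :-2], "n": zp[:-2, 1:-1], "ne": zp[:-2, 2:],
        "w": zp[1:-1, :-2],                     "e": zp[1:-1, 2:],
        "sw": zp[2:, :-2],  "s": zp[2:, 1:-1],  "se": zp[2:, 2:],
    }


def slope_aspect(dem: Raster) -> tuple[Raster, Raster, Raster, Raster]:
    """Slope, aspect and the aspect components via Horn's method.

    Returns (SLOPE_DEG, aspect, EASTNESS, NORTHNESS).  Aspect is in
    radians clockwise from north, pointing downslope; it is NaN where the
    local gradient vanishes, in which case the components are set to 0
    (direction-neutral).  NoData neighbors take the focal value, which
    makes the stencil usable up to the coast without imputing sea.
    """
    if min(dem.shape) < 3:
        raise ValueError("DEM must be at least 3x3")
    z = dem.data
    nb = _neighbor_shifts(z)
    nb = {k: np.where(np.isfinite(v), v, z) for k, v in nb.items()}
    cell = dem.cell_m
    dzdx = ((nb["ne"] + 2 * nb["e"] + nb["se"]) - (nb["nw"] + 2 * nb["w"] + nb["sw"])) / (8 * cell)
    dzdy = ((nb["nw"] + 2 * nb["n"] + nb["ne"]) - (nb["sw"] + 2 * nb["s"] + nb["se"])) / (8 * cell)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.mod(np.arctan2(-dzdx, -dzdy), 2 * np.pi)
    aspect = np.where(grad > 0, aspect, np.nan)
    east = np.where(np.isfinite(aspect), np.sin(aspect), 0.0)
    north = np.where(np.isfinite(aspect), np.cos(aspect), 0.0)
    land = dem.mask
    out = lambda a: dem.copy_with(np.where(land, a, np.nan))
    return out(slope), out(aspect), out(east), out(north)


def tri(dem: Raster) -> Raster:
    """Terrain ruggedness: RMS elevation difference to available neighbors."""
    if min(dem.shape) < 2:
        raise ValueError("DEM too small for TRI")
    z = dem.data
    sq_sum = np.zeros_like(z)
    count = np.zeros_like(z)
    for v in _neighbor_shifts(z).values():
        valid = np.isfinite(v)
        d = np.where(valid, v - z, 0.0)
        sq_sum += np.where(valid, d * d, 0.0)
        count += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(sq_sum / count)
    return dem.copy_with(np.where(dem.mask & (count > 0), out, np.nan))


def _disk_footprint(radius_cells: int, exclude_center: bool = False) -> np.ndarray:
    n = 2 * radius_cells + 1
    yy, xx = np.mgrid[-radius_cells : radius_cells + 1, -radius_cells : radius_cells + 1]
    fp = (xx * xx + yy * yy) <= radius_cells * radius_cells
    if exclude_center:
        fp[radius_cells, radius_cells] = False
    return fp.astype(float).reshape(n, n)


def _focal_sum(values: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Windowed sum with zero padding, via FFT convolution."""
    out = signal.fftconvolve(values, footprint, mode="same")
    return out


def tpi(dem: Raster, radius_m: float) -> Raster:
    """Topographic position: elevation minus circular-window land mean.

    The focal cell is excluded from the window mean; cells whose window
    contains no other land cell become NoData.
    """
    if radius_m < dem.cell_m:
        raise ValueError("radius must be at least one cell")
    rad = int(round(radius_m / dem.cell_m))
    fp = _disk_footprint(rad, exclude_center=True)
    land = dem.mask.astype(float)
    zfill = np.where(dem.mask, dem.data, 0.0)
    s = _focal_sum(zfill, fp)
    c = _focal_sum(land, fp)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / c
    out = dem.data - mean
    out = np.where(dem.mask & (np.round(c) > 0), out, np.nan)
    return dem.copy_with(out)


def dist_coast(land_mask: Raster, shoreline=None) -> Raster:
    """Euclidean distance (m) from each land-cell center to the shoreline.

    Declared convention: the shoreline runs along the land/sea cell
    interface, so the distance is the Euclidean-distance-transform value
    to the nearest sea-cell center minus half a cell, clipped at 0.  The
    grid border counts as sea, so land touching the border is coastal.
    A cell whose center lies on the boundary reads 0 within cell_m/2.
    """
    land = land_mask.mask & (np.nan_to_num(land_mask.data) > 0)
    if not land.any():
        raise ValueError("no land cells")
    padded = np.pad(land, 1, constant_values=False)
    d = ndimage.distance_transform_edt(padded, sampling=land_mask.cell_m)
    d = d[1:-1, 1:-1] - land_mask.cell_m / 2.0
    d = np.clip(d, 0.0, None)
    return land_mask.copy_with(np.where(land, d, np.nan))


# McCune & Keon (2002) heat-load equation coefficients (their eq. for
# folded aspect, all-aspect form): HL = exp(-1.467 + 1.582 cosL cosS
# - 1.500 cosA sinS cosL - 0.262 sinL sinS + 0.607 sinA sinS), with
# A = folded aspect |pi - |aspect - 5pi/4|| (fold about the SW axis).
_HL_COEF = (-1.467, 1.582, -1.500, -0.262, 0.607)


def heat_load(slope_deg: Raster, aspect: Raster, latitude_deg: float) -> Raster:
    """McCune-Keon heat-load index from slope, aspect and latitude.

    Aspect is folded about the southwest axis so SW-facing slopes score
    highest.  Where aspect is undefined (flat cells) the aspect terms
    vanish with sin(slope)=0, so a neutral folded aspect of pi/2 is used.
    """
    if not -90 < latitude_deg < 90:
        raise ValueError("latitude out of range")
    lat = np.radians(latitude_deg)
    s = np.radians(slope_deg.data)
    a = aspect.data
    folded = np.where(np.isfinite(a), np.abs(np.pi - np.abs(a - 5 * np.pi / 4)), np.pi / 2)
    c0, c1, c2, c3, c4 = _HL_COEF
    hl = np.exp(
        c0
        + c1 * np.cos(lat) * np.cos(s)
        + c2 * np.cos(folded) * np.sin(s) * np.cos(lat)
        + c3 * np.sin(lat) * np.sin(s)
        + c4 * np.sin(folded) * np.sin(s)
    )
    return slope_deg.copy_with(np.where(slope_deg.mask, hl, np.nan))


def _minmax01(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    lo = np.nanmin(np.where(mask, values, np.nan))
    hi = np.nanmax(np.where(mask, values, np.nan))
    if hi - lo <= 0:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def twi_proxy(dem: Raster, slope_deg: Raster, relief_radius_m: float) -> Raster:
    """Wetness proxy: -(scaled local relief) - (scaled slope).

    Relief is the max-min elevation over a circular window of land cells.
    Both terms are min-max rescaled to [0, 1] island-wide before the
    (negated) sum, so the result lies in [-2, 0] with 0 = flattest,
    wettest conditions.  This is a deliberate proxy, not the classic
    ln(a/tan b) wetness index.
    """
    if relief_radius_m < dem.cell_m:
        raise ValueError("radius must be at least one cell")
    rad = int(round(relief_radius_m / dem.cell_m))
    fp = _disk_footprint(rad).astype(bool)
    zmax = ndimage.maximum_filter(np.where(dem.mask, dem.data, -np.inf), footprint=fp,
                                  mode="constant", cval=-np.inf)
    zmin = ndimage.minimum_filter(np.where(dem.mask, dem.data, np.inf), footprint=fp,
                                  mode="constant", cval=np.inf)
    relief = zmax - zmin
    land = dem.mask
    relief_s = _minmax01(relief, land)
    slope_s = _minmax01(slope_deg.data, land)
    out = -relief_s - slope_s
    return dem.copy_with(np.where(land, out, np.nan))


def _coast_adjacent(land: np.ndarray) -> np.ndarray:
    """Land cells with at least one sea 8-neighbor (grid border = sea)."""
    sea = np.pad(~land, 1, constant_values=True)
    any_sea = np.zeros_like(land)
    for v in _neighbor_shifts(sea.astype(float)).values():
        any_sea |= v[1:-1, 1:-1] > 0
    return land & any_sea


def coastal_exposure(
    dem: Raster,
    land_mask: Raster,
    shoreline=None,
    config: TerrainConfig | None = None,
) -> tuple[Raster, Raster, Raster]:
    """WAVE_EXP, EDGE_SLOPE and CLIFF_NEAR from DEM and shoreline geometry.

    WAVE_EXP = exp(-DIST_COAST_M/decay) x seaward openness, where openness
    is the fraction of 16 compass rays from the cell center that reach sea
    within the decay length.  EDGE_SLOPE is the mean slope of
    shoreline-adjacent cells within the decay radius (0 if none).
    CLIFF_NEAR is the Euclidean distance to the nearest cell with slope at
    or above the cliff threshold (a large sentinel when none exists).
    """
    config = config or TerrainConfig()
    land = land_mask.mask & (np.nan_to_num(land_mask.data) > 0)
    cell = dem.cell_m
    decay = config.exposure_decay_m
    slope, _aspect, _e, _n = slope_aspect(dem)
    dcoast = dist_coast(land_mask)

    # seaward openness over 16 compass rays, stepping one cell at a time
    nsteps = max(1, int(np.ceil(decay / cell)))
    sea_pad = np.pad(~land, nsteps, constant_values=True)
    nrow, ncol = land.shape
    reached = np.zeros((16,) + land.shape, dtype=bool)
    for k in range(16):
        theta = k * (2 * np.pi / 16)  # clockwise from north
        for t in range(1, nsteps + 1):
            dr = -int(round(t * np.cos(theta)))
            dc = int(round(t * np.sin(theta)))
            window = sea_pad[nsteps + dr : nsteps + dr + nrow, nsteps + dc : nsteps + dc + ncol]
            reached[k] |= window
    openness = reached.mean(axis=0)
    wave = np.exp(-np.where(land, dcoast.data, 0.0) / decay) * openness

    # mean slope of coast-adjacent cells within the decay radius
    edge = _coast_adjacent(land)
    rad = max(1, int(round(decay / cell)))
    fp = _disk_footprint(rad)
    s_sum = _focal_sum(np.where(edge, slope.data, 0.0), fp)
    s_cnt = _focal_sum(edge.astype(float), fp)
    with np.errstate(invalid="ignore", divide="ignore"):
        edge_slope = np.where(np.round(s_cnt) > 0, s_sum / np.maximum(s_cnt, 1e-12), 0.0)

    # distance to the nearest cliff cell
    cliff = land & (slope.data >= config.cliff_slope_deg)
    if cliff.any():
        cliff_near = ndimage.distance_transform_edt(~cliff, sampling=cell)
    else:
        cliff_near = np.full(land.shape, CLIFF_SENTINEL_M)

    out = lambda a: dem.copy_with(np.where(land, a, np.nan))
    return out(wave), out(edge_slope), out(cliff_near)


def derive_predictors(dem: Raster, config: TerrainConfig | None = None) -> PredictorStack:
    """Build the full 12-layer predictor stack from a DEM."""
    config = config or TerrainConfig()
    land_mask = dem.copy_with(np.where(dem.mask, 1.0, np.nan))
    slope, aspect, east, north = slope_aspect(dem)
    wave, edge_slope, cliff = coastal_exposure(dem, land_mask, config=config)
    layers = {
        "ELEV_M": dem,
        "SLOPE_DEG": slope,
        "TRI": tri(dem),
        "TPI": tpi(dem, config.tpi_radius_m),
        "EASTNESS": east,
        "NORTHNESS": north,
        "DIST_COAST_M": dist_coast(land_mask),
        "HEAT_LOAD": heat_load(slope, aspect, config.latitude_deg),
        "TWI_APPROX": twi_proxy(dem, slope, config.relief_radius_m),
        "WAVE_EXP": wave,
        "EDGE_SLOPE": edge_slope,
        "CLIFF_NEAR": cliff,
    }
    return PredictorStack(layers)


def _block_nanmean(a: np.ndarray, factor: int) -> np.ndarray:
    nrow, ncol = a.shape
    pr = (-nrow) % factor
    pc = (-ncol) % factor
    if pr or pc:
        a = np.pad(a, ((0, pr), (0, pc)), constant_values=np.nan)
    nr, nc = a.shape[0] // factor, a.shape[1] // factor
    blocks = a.reshape(nr, factor, nc, factor).transpose(0, 2, 1, 3).reshape(nr, nc, -1)
    with np.errstate(invalid="ignore"):
        counts = np.isfinite(blocks).sum(axis=-1)
        out = np.where(counts > 0, np.nansum(blocks, axis=-1) / np.maximum(counts, 1), np.nan)
    return out


def scale_transfer(
    stack: PredictorStack, fit_cell_m: float, map_cell_m: float
) -> tuple[PredictorStack, PredictorStack]:
    """Aggregate the native stack to the fitting scale.

    Returns (fit_stack, map_stack): the fit stack averages contributing
    land cells per block (mean over non-NoData), the map stack is the
    native-resolution input.  Because the model is a fixed coefficient
    vector over scaled features, it evaluates per-cell on either stack.
    """
    if stack.cell_m != map_cell_m:
        raise ValueError("stack resolution does not match map_cell_m")
    ratio = fit_cell_m / map_cell_m
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("fit_cell_m must be an integer multiple of map_cell_m")
    factor = int(round(ratio))
    if factor == 1:
        return stack, stack
    # blocks grow from the top-left corner; keep the top edge fixed so the
    # lower-left origin moves down when nrow is not a multiple of factor
    nrow = stack.shape[0]
    ytop = stack.origin[1] + nrow * map_cell_m
    layers = {}
    for name in stack:
        agg = _block_nanmean(stack[name].data, factor)
        origin = (stack.origin[0], ytop - agg.shape[0] * fit_cell_m)
        layers[name] = Raster(agg, cell_m=fit_cell_m, origin=origin,
                              crs_epsg=stack[name].crs_epsg)
    return PredictorStack(layers), stack
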