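import numpy as np
import pytest

from coastcore.grids import Raster
from coastcore import terrain
from coastcore.terrain import (
    PredictorStack,
    TerrainConfig,
    coastal_exposure,
    dist_coast,
    heat_load,
    scale_transfer,
    slope_aspect,
    tpi,
    tri,
    twi_proxy,
)


def raster(data, cell=5.0):
    return Raster(np.asarray(data, dtype=float), cell_m=cell)


def horn_oracle(z, cell):
    """Independent per-cell Horn stencil with edge replication."""
    n, m = z.shape
    zp = np.pad(z, 1, mode="edge")
    slope = np.empty_like(z)
    aspect = np.empty_like(z)
    for i in range(n):
        for j in range(m):
            a, b, c = zp[i, j], zp[i, j + 1], zp[i, j + 2]
            d, _, f = zp[i + 1, j], zp[i + 1, j + 1], zp[i + 1, j + 2]
            g, h, k = zp[i + 2, j], zp[i + 2, j + 1], zp[i + 2, j + 2]
            dzdx = ((c + 2 * f + k) - (a + 2 * d + g)) / (8 * cell)
            dzdy = ((a + 2 * b + c) - (g + 2 * h + k)) / (8 * cell)
            slope[i, j] = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
            aspect[i, j] = np.mod(np.arctan2(-dzdx, -dzdy), 2 * np.pi)
    return slope, aspect


class TestSlopeAspect:
    def test_flat_dem(self):
        s, a, e, n = slope_aspect(raster(np.zeros((4, 4))))
        np.testing.assert_allclose(s.data, 0.0)
        assert np.isnan(a.data).all()
        np.testing.assert_allclose(e.data, 0.0)
        np.testing.assert_allclose(n.data, 0.0)

    def test_east_rising_plane_faces_west(self):
        xx = np.tile(np.arange(5, dtype=float) * 5.0, (5, 1))
        s, a, e, n = slope_aspect(raster(xx))
        # edge columns see replicated neighbors, so check slope away from them
        np.testing.assert_allclose(s.data[:, 1:-1], 45.0)
        np.testing.assert_allclose(a.data, 3 * np.pi / 2)  # downslope = west
        np.testing.assert_allclose(e.data, -1.0)
        np.testing.assert_allclose(n.data, 0.0, atol=1e-12)

    def test_random_dem_matches_horn_oracle(self, rng):
        z = rng.normal(0, 10, (5, 5))
        s, a, _, _ = slope_aspect(raster(z))
        so, ao = horn_oracle(z, 5.0)
        np.testing.assert_allclose(s.data, so, atol=1e-10)
        np.testing.assert_allclose(a.data, ao, atol=1e-10)

    def test_aspect_component_norm(self, rng):
        z = rng.normal(0, 10, (6, 6))
        _, _, e, n = slope_aspect(raster(z))
        assert np.all(e.data**2 + n.data**2 <= 1 + 1e-9)

    def test_tiny_dem_rejected(self):
        with pytest.raises(ValueError):
            slope_aspect(raster([[1.0]]))


class TestTri:
    def test_flat(self):
        assert np.allclose(tri(raster(np.zeros((4, 4)))).data, 0.0)

    def test_center_spike(self):
        z = np.zeros((3, 3))
        z[1, 1] = 1.0
        out = tri(raster(z))
        assert out.data[1, 1] == pytest.approx(1.0)

    def test_matches_neighbor_loop_oracle(self, rng):
        z = rng.normal(0, 5, (5, 5))
        out = tri(raster(z)).data
        zp = np.pad(z, 1, mode="edge")
        for i in range(5):
            for j in range(5):
                diffs = []
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        diffs.append(zp[i + 1 + di, j + 1 + dj] - z[i, j])
                assert out[i, j] == pytest.approx(np.sqrt(np.mean(np.square(diffs))))


class TestTpi:
    def test_constant(self):
        out = tpi(raster(np.full((7, 7), 3.0)), radius_m=10)
        assert np.allclose(out.data, 0.0)

    def test_peak_positive(self):
        z = np.zeros((7, 7))
        z[3, 3] = 10.0
        assert tpi(raster(z), radius_m=10).data[3, 3] > 0

    def test_matches_window_enumeration(self, rng):
        z = rng.normal(0, 5, (7, 7))
        rad_cells = 2
        out = tpi(raster(z), radius_m=rad_cells * 5.0).data
        for i in range(7):
            for j in range(7):
                vals = []
                for di in range(-rad_cells, rad_cells + 1):
                    for dj in range(-rad_cells, rad_cells + 1):
                        if di == dj == 0 or di * di + dj * dj > rad_cells**2:
                            continue
                        ii, jj = i + di, j + dj
                        if 0 <= ii < 7 and 0 <= jj < 7:
                            vals.append(z[ii, jj])
                assert out[i, j] == pytest.approx(z[i, j] - np.mean(vals), abs=1e-9)

    def test_islandwide_mean_near_zero(self):
        from coastcore.island import IslandConfig, generate_dem

        dem = generate_dem(IslandConfig(seed=42))
        out = tpi(dem, radius_m=90.0)
        vals = out.data[np.isfinite(out.data)]
        assert abs(vals.mean()) < 0.05 * vals.std()


class TestDistCoast:
    def test_strip_distances(self, strip_raster):
        out = dist_coast(strip_raster)
        got = out.data[1, 1:5]
        np.testing.assert_allclose(got, [2.5, 2.5, 2.5, 2.5])
        # cells in a 1-wide strip are all shoreline-adjacent; use a wider toy
        data = np.full((9, 9), np.nan)
        data[1:8, 1:8] = 1.0
        out = dist_coast(Raster(data, cell_m=5.0))
        np.testing.assert_allclose(out.data[4, 1:5], [2.5, 7.5, 12.5, 17.5])

    def test_matches_brute_force(self, rng):
        land = rng.uniform(size=(20, 20)) > 0.4
        land[0, :] = land[-1, :] = land[:, 0] = land[:, -1] = False
        mask = Raster(np.where(land, 1.0, np.nan), cell_m=5.0)
        out = dist_coast(mask).data
        sea = np.pad(~land, 1, constant_values=True)
        si, sj = np.nonzero(sea)
        for i, j in zip(*np.nonzero(land)):
            d = np.min(np.hypot(si - (i + 1), sj - (j + 1))) * 5.0 - 2.5
            assert out[i, j] == pytest.approx(max(d, 0.0))

    def test_lipschitz(self):
        from coastcore.island import IslandConfig, generate_dem

        dem = generate_dem(IslandConfig(seed=42, grid_size=128))
        mask = dem.copy_with(np.where(dem.mask, 1.0, np.nan))
        d = dist_coast(mask).data
        dx = np.abs(np.diff(d, axis=1))
        assert np.nanmax(dx) <= 5.0 + 1e-9

    def test_empty_land_rejected(self):
        with pytest.raises(ValueError):
            dist_coast(Raster(np.full((3, 3), np.nan), cell_m=5.0))


class TestHeatLoad:
    def test_flat_slope_aspect_free(self):
        s = raster(np.zeros((3, 3)))
        for asp in (0.0, np.pi / 2, np.pi):
            a = raster(np.full((3, 3), asp))
            out = heat_load(s, a, 37.5)
            np.testing.assert_allclose(out.data, out.data[0, 0])

    def test_sw_hotter_than_ne(self):
        s = raster(np.full((3, 3), 25.0))
        sw = heat_load(s, raster(np.full((3, 3), 5 * np.pi / 4)), 37.5)
        ne = heat_load(s, raster(np.full((3, 3), np.pi / 4)), 37.5)
        assert np.all(sw.data > ne.data)

    def test_matches_scalar_formula(self):
        lat, slope_deg, aspect = np.radians(37.5), 20.0, np.pi  # south-facing
        folded = abs(np.pi - abs(aspect - 5 * np.pi / 4))
        s = np.radians(slope_deg)
        expected = np.exp(
            -1.467
            + 1.582 * np.cos(lat) * np.cos(s)
            - 1.500 * np.cos(folded) * np.sin(s) * np.cos(lat)
            - 0.262 * np.sin(lat) * np.sin(s)
            + 0.607 * np.sin(folded) * np.sin(s)
        )
        out = heat_load(raster(np.full((3, 3), slope_deg)),
                        raster(np.full((3, 3), aspect)), 37.5)
        assert out.data[1, 1] == pytest.approx(expected)


class TestTwiProxy:
    def test_flat_dem_max_everywhere(self):
        dem = raster(np.zeros((7, 7)))
        s = raster(np.zeros((7, 7)))
        out = twi_proxy(dem, s, relief_radius_m=10)
        np.testing.assert_allclose(out.data, 0.0)

    def test_valley_wetter_than_ridge(self):
        from coastcore.island import IslandConfig, generate_dem

        dem = generate_dem(IslandConfig(seed=42))
        s, *_ = slope_aspect(dem)
        out = twi_proxy(dem, s, 90.0)
        flat = dem.mask & (s.data < np.nanpercentile(s.data, 10))
        steep = dem.mask & (s.data > np.nanpercentile(s.data, 90))
        assert np.nanmean(out.data[flat]) > np.nanmean(out.data[steep])

    def test_matches_window_oracle(self, rng):
        z = rng.normal(0, 5, (9, 9))
        dem = raster(z)
        s, *_ = slope_aspect(dem)
        rad = 2
        out = twi_proxy(dem, s, rad * 5.0).data
        relief = np.empty_like(z)
        for i in range(9):
            for j in range(9):
                vals = []
                for di in range(-rad, rad + 1):
                    for dj in range(-rad, rad + 1):
                        if di * di + dj * dj > rad * rad:
                            continue
                        ii, jj = i + di, j + dj
                        if 0 <= ii < 9 and 0 <= jj < 9:
                            vals.append(z[ii, jj])
                relief[i, j] = max(vals) - min(vals)
        r_s = (relief - relief.min()) / (relief.max() - relief.min())
        sl = s.data
        s_s = (sl - np.nanmin(sl)) / (np.nanmax(sl) - np.nanmin(sl))
        expected = -r_s - s_s
        np.testing.assert_allclose(out, expected, atol=1e-9)


@pytest.fixture(scope="module")
def island_layers():
    from coastcore.island import IslandConfig, generate_dem

    dem = generate_dem(IslandConfig(seed=42, grid_size=128))
    mask = dem.copy_with(np.where(dem.mask, 1.0, np.nan))
    wave, edge, cliff = coastal_exposure(dem, mask, config=TerrainConfig())
    return dem, mask, wave, edge, cliff


class TestCoastalExposure:

    def test_wave_decays_inland(self, island_layers):
        dem, mask, wave, _, _ = island_layers
        d = dist_coast(mask)
        far = dem.mask & (d.data > 5 * 200.0)
        if far.any():
            assert np.nanmax(wave.data[far]) < 0.01
        near = dem.mask & (d.data < 10.0)
        assert np.nanmean(wave.data[near]) > np.nanmean(wave.data[dem.mask])

    def test_openness_bounds(self, island_layers):
        *_, wave, _, _ = island_layers
        vals = wave.data[np.isfinite(wave.data)]
        assert np.all(vals >= 0) and np.all(vals <= 1 + 1e-9)

    def test_cliff_near_matches_exhaustive_search(self):
        # flat toy with one steep cell
        z = np.zeros((12, 12))
        z[5, 5] = 100.0  # creates steep slopes around (5,5)
        dem = raster(z)
        mask = dem.copy_with(np.ones((12, 12)))
        cfg = TerrainConfig(cliff_slope_deg=40.0)
        _, _, cliff = coastal_exposure(dem, mask, config=cfg)
        slope, *_ = slope_aspect(dem)
        ci, cj = np.nonzero(slope.data >= 40.0)
        assert len(ci) > 0
        for i in range(12):
            for j in range(12):
                d = np.min(np.hypot(ci - i, cj - j)) * 5.0
                assert cliff.data[i, j] == pytest.approx(d)

    def test_no_cliffs_gives_sentinel(self):
        dem = raster(np.zeros((8, 8)))
        mask = dem.copy_with(np.ones((8, 8)))
        _, _, cliff = coastal_exposure(dem, mask, config=TerrainConfig())
        assert np.all(cliff.data == terrain.CLIFF_SENTINEL_M)


class TestScaleTransfer:
    def _stack(self, data):
        return PredictorStack({"ELEV_M": raster(data)})

    def test_constant_layer_unchanged(self):
        fit, _ = scale_transfer(self._stack(np.full((36, 36), 7.0)), 90.0, 5.0)
        assert fit.cell_m == 90.0
        np.testing.assert_allclose(fit["ELEV_M"].data, 7.0)

    def test_block_mean_oracle(self, rng):
        data = rng.normal(0, 1, (36, 36))
        data[rng.uniform(size=(36, 36)) < 0.2] = np.nan
        fit, _ = scale_transfer(self._stack(data), 90.0, 5.0)
        factor = 18
        for bi in range(2):
            for bj in range(2):
                block = data[bi * factor : (bi + 1) * factor, bj * factor : (bj + 1) * factor]
                expected = np.nanmean(block)
                assert fit["ELEV_M"].data[bi, bj] == pytest.approx(expected)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            scale_transfer(self._stack(np.zeros((10, 10))), 12.0, 5.0)

    def test_identity_when_scales_match(self):
        stack = self._stack(np.zeros((10, 10)))
        fit, mp = scale_transfer(stack, 5.0, 5.0)
        assert fit is stack and mp is stack


class TestPredictorStack:
    def test_co_registration_enforced(self):
        with pytest.raises(ValueError):
            PredictorStack({"a": raster(np.zeros((3, 3))), "b": raster(np.zeros((4, 4)))})

    def test_extract_at_xy_out_of_grid_nan(self):
        stack = PredictorStack({"a": raster(np.ones((4, 4)))})
        rows = stack.extract_at_xy(np.array([2.5, 1000.0]), np.array([2.5, 1000.0]))
        assert np.isfinite(rows[0, 0])
        assert np.isnan(rows[1, 0])

    def test_full_stack_finite_on_land(self, design42):
        stack = design42.stack
        land = design42.dem.mask
        for name in terrain.CANONICAL_LAYERS:
            assert np.all(np.isfinite(stack[name].data[land])), name
            assert np.all(np.isnan(stack[name].data[~land])), name
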