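"""Gradients, climate velocity, regional summaries, anomaly trends."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from strandshift import climate_fields as cf
from strandshift.shelf_geometry import KM_PER_DEG
from strandshift.synthetic_data import WorldSpec, build_world, gen_sst_cube


def flat_cube(nlat=12, nlon=10, nyear=10, fill=10.0):
    lat = 30 + 0.25 * np.arange(nlat)
    lon = -75 + 0.25 * np.arange(nlon)
    year = 1996 + np.arange(nyear)
    data = np.full((nlat, nlon, nyear), fill, dtype=float)
    return xr.DataArray(data, coords={"lat": lat, "lon": lon, "year": year}, dims=("lat", "lon", "year"))


class TestTemporalGradient:
    def test_exact_linear_warming_recovered(self):
        cube = flat_cube()
        cube = cube + 0.05 * xr.DataArray(np.arange(10), dims="year", coords={"year": cube["year"]})
        g = cf.temporal_gradient(cube)
        assert np.allclose(g.values, 0.05, atol=1e-12)

    def test_constant_sst_gives_zero(self):
        g = cf.temporal_gradient(flat_cube())
        assert np.allclose(g.values, 0.0, atol=1e-12)

    def test_matches_closed_form_ols_per_cell(self):
        rng = np.random.default_rng(0)
        cube = flat_cube()
        cube = cube + xr.DataArray(rng.normal(0, 1, cube.shape), coords=cube.coords, dims=cube.dims)
        g = cf.temporal_gradient(cube).values
        t = cube["year"].values.astype(float)
        tc = t - t.mean()
        oracle = (cube.values * tc).sum(-1) / (tc**2).sum()
        assert np.allclose(g, oracle, atol=1e-10)

    def test_cells_with_too_few_years_masked(self):
        cube = flat_cube()
        v = cube.values
        v[0, 0, :] = np.nan
        v[1, 1, 2:] = np.nan  # only 2 valid years
        g = cf.temporal_gradient(cube)
        assert np.isnan(g.values[0, 0]) and np.isnan(g.values[1, 1])


class TestSpatialGradient:
    def test_north_south_plane(self):
        cube = flat_cube()
        y_km = (cube["lat"].values - cube["lat"].values[0]) * KM_PER_DEG
        cube = cube + xr.DataArray(0.01 * y_km, dims="lat", coords={"lat": cube["lat"]})
        g = cf.spatial_gradient(cube).values
        assert np.allclose(g[1:-1, 1:-1], 0.01, atol=1e-12)

    def test_three_four_five_magnitude(self):
        # equator-centered grid so the east-west km scale is uniform and the
        # planar construction is exact
        nlat, nlon = 12, 10
        lat = -1.5 + 0.25 * np.arange(nlat)
        lon = -75 + 0.25 * np.arange(nlon)
        y_km = (lat - lat[0]) * KM_PER_DEG
        x_km = (lon[None, :] - lon[0]) * KM_PER_DEG * np.cos(np.radians(lat))[:, None]
        plane = 10.0 + 0.003 * y_km[:, None] + 0.004 * x_km
        cube = xr.DataArray(
            np.repeat(plane[:, :, None], 5, axis=2),
            coords={"lat": lat, "lon": lon, "year": 2000 + np.arange(5)},
            dims=("lat", "lon", "year"),
        )
        g = cf.spatial_gradient(cube).values
        assert np.allclose(g[1:-1, 1:-1], 0.005, atol=1e-5)

    def test_uniform_field_zero_gradient_velocity_masked(self):
        cube = flat_cube()
        g = cf.spatial_gradient(cube)
        assert np.allclose(g.values[1:-1, 1:-1], 0.0, atol=1e-12)
        v = cf.climate_velocity(cf.temporal_gradient(cube), g)
        assert not v.valid.values.any()
        assert np.isnan(v.velocity.values).all()


class TestClimateVelocity:
    def test_ratio(self):
        gt = xr.DataArray(np.full((4, 4), 0.05), dims=("lat", "lon"))
        gr = xr.DataArray(np.full((4, 4), 0.01), dims=("lat", "lon"))
        v = cf.climate_velocity(gt, gr)
        assert np.allclose(v.velocity.values, 5.0)

    def test_cooling_gives_negative_velocity(self):
        gt = xr.DataArray(np.full((3, 3), -0.02), dims=("lat", "lon"))
        gr = xr.DataArray(np.full((3, 3), 0.01), dims=("lat", "lon"))
        v = cf.climate_velocity(gt, gr).velocity.values
        assert (v < 0).all()

    def test_velocity_scales_linearly_with_warming_rate(self):
        gt = xr.DataArray(np.linspace(0.01, 0.09, 9).reshape(3, 3), dims=("lat", "lon"))
        gr = xr.DataArray(np.full((3, 3), 0.01), dims=("lat", "lon"))
        v1 = cf.climate_velocity(gt, gr).velocity.values
        v2 = cf.climate_velocity(2 * gt, gr).velocity.values
        assert np.allclose(v2, 2 * v1)

    def test_shape_mismatch_raises(self):
        gt = xr.DataArray(np.zeros((3, 3)), dims=("lat", "lon"))
        gr = xr.DataArray(np.zeros((4, 4)), dims=("lat", "lon"))
        with pytest.raises(ValueError, match="align"):
            cf.climate_velocity(gt, gr)


class TestRegionalSummary:
    def test_identical_cells(self):
        f = xr.DataArray(np.full((5, 5), 5.0), dims=("lat", "lon"))
        s = cf.regional_summary(f, np.ones((5, 5), bool))
        assert (s.median, s.q25, s.q75) == (5.0, 5.0, 5.0)

    def test_order_statistics_1_to_100(self):
        f = xr.DataArray(np.arange(1.0, 101.0).reshape(10, 10), dims=("lat", "lon"))
        s = cf.regional_summary(f, np.ones((10, 10), bool))
        assert s.median == pytest.approx(50.5)

    def test_masked_cells_excluded(self):
        vals = np.arange(1.0, 101.0).reshape(10, 10)
        vals[0, :] = np.nan  # drop 1..10
        f = xr.DataArray(vals, dims=("lat", "lon"))
        s = cf.regional_summary(f, np.ones((10, 10), bool))
        assert s.n_cells == 90
        assert s.median == pytest.approx(55.5)

    def test_empty_region_raises(self):
        f = xr.DataArray(np.ones((3, 3)), dims=("lat", "lon"))
        with pytest.raises(ValueError, match="region"):
            cf.regional_summary(f, np.zeros((3, 3), bool))

    def test_area_weighting_matters_only_when_cell_areas_differ(self):
        # values correlated with latitude over a wide band: weighting shifts quantiles
        lat_wide = np.array([10.0, 30.0, 50.0, 70.0])
        vals = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 5))
        f_wide = xr.DataArray(vals, coords={"lat": lat_wide, "lon": np.arange(5.0)}, dims=("lat", "lon"))
        mask = np.ones(vals.shape, bool)
        unw = cf.regional_summary(f_wide, mask)
        wtd = cf.regional_summary(f_wide, mask, area_weighted=True)
        assert wtd.median < unw.median  # low-latitude (large) cells pull the median down

        # single-latitude region: all cells equal area, weighting is a no-op
        f_row = xr.DataArray(np.arange(1.0, 6.0)[None, :],
                             coords={"lat": [40.0], "lon": np.arange(5.0)}, dims=("lat", "lon"))
        rmask = np.ones((1, 5), bool)
        a = cf.regional_summary(f_row, rmask)
        b = cf.regional_summary(f_row, rmask, area_weighted=True)
        assert b.median == pytest.approx(a.median)


@pytest.fixture(scope="module")
def world():
    return build_world(WorldSpec(grid_shape=(60, 16), cell_km=15.0))


class TestAnomalySeries:
    def test_anomalies_center_on_baseline(self, world):
        cube = gen_sst_cube(world, temporal_gradient=0.05, noise_sd=0.1, seed=1)
        anom, _ = cf.sst_anomaly_series(cube, ~world.grid.land_mask)
        assert anom.sum() == pytest.approx(0.0, abs=1e-9)

    def test_prescribed_warming_rate_recovered(self, world):
        """Regional anomaly trend of a cube built at the observed NEUS rate."""
        cube = gen_sst_cube(world, temporal_gradient=0.062, noise_sd=0.15, seed=3)
        _, fit = cf.sst_anomaly_series(cube, ~world.grid.land_mask)
        # regional averaging over ~700 sea cells crushes the noise
        assert fit.slope == pytest.approx(0.062, abs=0.005)

    def test_zero_trend_cube_ci_covers_zero(self, world):
        from scipy import stats

        covered = 0
        for seed in range(30):
            cube = gen_sst_cube(world, temporal_gradient=0.0, noise_sd=0.3, seed=seed)
            anom, fit = cf.sst_anomaly_series(cube, ~world.grid.land_mask)
            res = stats.linregress(anom.index, anom.values)
            t = stats.t.ppf(0.975, anom.size - 2)
            if abs(res.slope) <= t * res.stderr:
                covered += 1
        assert covered >= 27  # >= 90% of seeds

    def test_empty_region_raises(self, world):
        cube = gen_sst_cube(world, noise_sd=0.0)
        with pytest.raises(ValueError, match="empty region"):
            cf.sst_anomaly_series(cube, np.zeros(world.grid.shape, bool))
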