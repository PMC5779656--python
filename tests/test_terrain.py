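"""Terrain covariates: burning, D8 routing, MRVBF, northness, solar."""

import numpy as np
import pytest

from ditchsdm.grids import Grid
from ditchsdm.terrain import (
    SolarConfig,
    TerrainConfig,
    burn_streams,
    d8_flow,
    ditch_slope,
    fill_pits,
    mrvbf,
    northness,
    solar_radiation,
    trace_d8_path,
)


def east_plane(n=5, top=100.0, drop=1.0, cell=2.0):
    """Plane dipping east: every cell flows one column east."""
    z = np.tile(top - drop * np.arange(n), (n, 1))
    return Grid(z, cell_size=cell)


class TestBurnStreams:
    def test_zero_depth_identity(self):
        dtm = east_plane()
        mask = dtm.like(np.zeros(dtm.shape))
        mask.data[2, 2] = 1
        out = burn_streams(dtm, mask, TerrainConfig(burn_depth=0.0))
        np.testing.assert_array_equal(out.data, dtm.data)

    def test_burn_changes_exactly_masked_cells(self):
        dtm = Grid(np.full((6, 6), 60.0))
        mask = dtm.like(np.zeros((6, 6)))
        mask.data[3, 1:5] = 1
        out = burn_streams(dtm, mask, TerrainConfig(burn_depth=1.0))
        assert np.all(out.data[3, 1:5] == 59.0)
        untouched = out.data.copy()
        untouched[3, 1:5] = 60.0
        np.testing.assert_array_equal(untouched, dtm.data)

    def test_misaligned_mask_rejected(self):
        dtm = east_plane(5)
        with pytest.raises(ValueError, match="misaligned"):
            burn_streams(dtm, Grid(np.zeros((4, 4))), TerrainConfig())

    def test_descent_from_burned_network_stays_on_network(self, small_scene):
        """After burning, D8 paths started on ditch cells follow the ditches."""
        cfg = TerrainConfig(burn_depth=1.0)
        burned = burn_streams(small_scene.dem, small_scene.network_mask, cfg)
        conditioned = fill_pits(burned, outlet=small_scene.outlet)
        directions, _ = d8_flow(conditioned)
        network = set(map(tuple, np.argwhere(small_scene.network_mask.data > 0)))
        rng = np.random.default_rng(0)
        nodes = sorted(network)
        for k in rng.choice(len(nodes), size=20, replace=False):
            path = trace_d8_path(directions, nodes[k])
            assert set(path) <= network


class TestD8:
    def test_tilted_plane_row_accumulation(self):
        """5x5 plane tilted east: drain along each row grows 4, 8, 12, 16, 20 m2."""
        _, drain = d8_flow(east_plane(5))
        for row in drain.data:
            np.testing.assert_allclose(row, [4.0, 8.0, 12.0, 16.0, 20.0])

    def test_ridge_cell_self_area_only(self):
        _, drain = d8_flow(east_plane(5))
        assert np.all(drain.data[:, 0] == 4.0)  # western edge: no upslope contributors

    def test_conservation_to_unique_outlet(self, small_scene):
        conditioned = fill_pits(small_scene.dem, outlet=small_scene.outlet)
        _, drain = d8_flow(conditioned)
        total = small_scene.dem.data.size * small_scene.dem.cell_area
        assert drain.data[small_scene.outlet] == pytest.approx(total)

    def test_drain_monotone_downstream(self, small_scene):
        conditioned = fill_pits(small_scene.dem, outlet=small_scene.outlet)
        directions, drain = d8_flow(conditioned)
        rng = np.random.default_rng(1)
        n = small_scene.dem.shape[0]
        for _ in range(10):
            start = (int(rng.integers(1, n - 1)), int(rng.integers(1, n - 1)))
            path = trace_d8_path(directions, start)
            vals = [drain.data[c] for c in path]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_unconditioned_pit_raises(self):
        z = np.full((7, 7), 50.0) + np.arange(7)[None, :]
        z[3, 3] = 10.0  # interior pit
        with pytest.raises(ValueError, match="pit"):
            d8_flow(Grid(z))

    def test_fill_pits_resolves_and_names_nothing(self):
        z = np.full((7, 7), 50.0) + np.arange(7)[None, :]
        z[3, 3] = 10.0
        d8_flow(fill_pits(Grid(z)))  # no error after conditioning


class TestDitchSlope:
    def test_flat_polyline_zero(self):
        dtm = Grid(np.full((5, 30), 80.0))
        line = np.array([dtm.cell_center(2, 1), dtm.cell_center(2, 26)])
        out = ditch_slope([line], dtm)
        assert out.data[2, 10] == 0.0

    def test_arithmetic_one_metre_over_fifty(self):
        """1 m drop over a 50 m polyline -> slope 0.02 on every covered cell."""
        z = np.tile(np.linspace(81.0, 80.0, 26), (5, 1))  # 1 m drop over 25 cells = 50 m
        dtm = Grid(z, cell_size=2.0)
        line = np.array([dtm.cell_center(2, 0), dtm.cell_center(2, 25)])
        out = ditch_slope([line], dtm)
        covered = np.isfinite(out.data[2])
        assert covered.sum() >= 25
        np.testing.assert_allclose(out.data[2][covered], 1.0 / 50.0)

    def test_zero_length_rejected(self):
        dtm = Grid(np.zeros((5, 5)))
        line = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="zero length"):
            ditch_slope([line], dtm)

    def test_plane_scene_matches_gradient(self):
        """Ditch slope on an inclined plane equals the plane gradient."""
        dtm = east_plane(20, drop=0.5)  # gradient 0.5 m / 2 m = 0.25
        line = np.array([dtm.cell_center(10, 0), dtm.cell_center(10, 19)])
        out = ditch_slope([line], dtm)
        vals = out.data[10][np.isfinite(out.data[10])]
        np.testing.assert_allclose(vals, 0.25, rtol=1e-6)


class TestMrvbf:
    def test_steep_uniform_slope_below_half(self):
        """Slope at/above the initial threshold everywhere -> non-valley index."""
        n = 81
        z = np.tile(0.20 * 2.0 * np.arange(n), (n, 1))  # 20 % slope
        out = mrvbf(Grid(z), TerrainConfig(mrvbf_steps=4))
        assert np.all(out.data < 0.5)

    def test_constant_grid_maximal_response(self):
        out = mrvbf(Grid(np.zeros((60, 60))), TerrainConfig(mrvbf_steps=3))
        assert np.all(out.data > 1.5)

    def test_u_valley_floor_large_valley(self):
        """Wide flat valley floor in steep walls scores as large valley (> 1.5)."""
        n = 90
        cols = np.arange(n, dtype=float)
        half_floor = 15
        wall = 0.30 * 2.0 * np.maximum(np.abs(cols - n / 2) - half_floor, 0.0)
        z = np.tile(wall, (n, 1))
        out = mrvbf(Grid(z), TerrainConfig(mrvbf_steps=4))
        floor = out.data[20:-20, n // 2 - 5 : n // 2 + 5]
        assert np.all(floor > 1.5)

    def test_index_non_increasing_in_slope(self):
        """All else equal, a steeper uniform tilt never raises the index."""
        n = 45
        vals = []
        for grade in (0.00, 0.04, 0.08, 0.16, 0.32):
            z = np.tile(grade * 2.0 * np.arange(n), (n, 1))
            out = mrvbf(Grid(z), TerrainConfig(mrvbf_steps=3))
            vals.append(float(out.data[n // 2, n // 2]))
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_requires_step(self):
        with pytest.raises(ValueError):
            TerrainConfig(mrvbf_steps=0)


class TestNorthness:
    def test_cardinal_planes(self):
        n = 30
        south_dip = Grid(np.tile(np.linspace(0.0, 29.0, n)[:, None], (1, n)))  # z rises southward
        # z rising southward => downslope points north => aspect 0 => +1
        out = northness(south_dip, smooth_window=1)
        assert np.allclose(out.data[5:-5, 5:-5], 1.0)
        north_dip = Grid(south_dip.data[::-1].copy())
        out2 = northness(north_dip, smooth_window=1)
        assert np.allclose(out2.data[5:-5, 5:-5], -1.0)

    def test_flat_is_zero_and_range(self, small_scene):
        flat = northness(Grid(np.zeros((20, 20))))
        assert np.all(flat.data == 0.0)
        out = northness(small_scene.dem)
        assert np.all((out.data >= -1.0) & (out.data <= 1.0))


class TestSolar:
    def make_flat(self, n=24, z=100.0):
        return Grid(np.full((n, n), z))

    def test_canopy_cells_zeroed(self):
        dtm = self.make_flat()
        dsm = dtm.copy()
        dsm.data[5, 5] += 1.5  # exactly the cutoff
        dsm.data[6, 6] += 3.0
        out = solar_radiation(dsm, dtm, SolarConfig(day_step=20, hour_step=2.0))
        assert out.data[5, 5] == 0.0 and out.data[6, 6] == 0.0
        assert out.data[10, 10] > 0.0

    def test_flat_unshaded_terrain_uniform(self):
        dtm = self.make_flat()
        out = solar_radiation(dtm, dtm, SolarConfig(day_step=20, hour_step=2.0))
        assert np.ptp(out.data) == pytest.approx(0.0)

    def test_equator_facing_receives_more(self):
        """At mid-northern latitude a south-facing slope outgains a north-facing one."""
        n = 30
        # z rising southward -> downslope faces north; reversed rows face south
        north_facing = Grid(np.tile(np.linspace(0.0, n - 1.0, n)[:, None] * 0.4, (1, n)))
        south_facing = Grid(north_facing.data[::-1].copy())
        cfg = SolarConfig(day_step=20, hour_step=2.0)
        s = solar_radiation(south_facing, south_facing, cfg, latitude=43.4)
        nn = solar_radiation(north_facing, north_facing, cfg, latitude=43.4)
        assert s.data[n // 2, n // 2] > nn.data[n // 2, n // 2]

    def test_nonnegative_and_transmittance_monotone(self):
        dtm = self.make_flat(16)
        lo = solar_radiation(dtm, dtm, SolarConfig(transmittance=0.5, day_step=30, hour_step=3.0))
        hi = solar_radiation(dtm, dtm, SolarConfig(transmittance=0.8, day_step=30, hour_step=3.0))
        assert np.all(lo.data >= 0.0)
        assert np.all(hi.data >= lo.data)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SolarConfig(transmittance=-0.1)
        with pytest.raises(ValueError, match="calendar"):
            SolarConfig(period=((13, 1), (6, 30)))
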