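"""Virtual landscape and virtual species generators."""

import math

import numpy as np
import pytest
from scipy import stats

from pftshift.synthetic_landscape import (
    CLIMATE_LAYERS,
    ClimateDelta,
    EnvStack,
    GridSpec,
    NicheSpec,
    apply_climate_delta,
    generate_landscape,
    sample_occurrences,
    true_suitability,
)


class TestGridSpec:
    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0, 5, 0, 1, 0, 1)
        with pytest.raises(ValueError):
            GridSpec(5, 5, 1, 1, 0, 1)

    def test_cell_centers_and_lookup_roundtrip(self, grid):
        lats = grid.lat_centers()
        lons = grid.lon_centers()
        assert lats[0] > lats[-1]  # row 0 is northernmost
        r, c = grid.cell_of(lons[3], lats[5])
        assert (r, c) == (5, 3)

    def test_half_open_cells_edge_point_goes_south_east(self, grid):
        # a point exactly on an interior edge belongs to the south/east cell
        lon_edge = grid.lon_min + 2 * grid.cell_width
        lat_edge = grid.lat_max - 3 * grid.cell_height
        r, c = grid.cell_of(lon_edge, lat_edge)
        assert (r, c) == (3, 2)


class TestGenerateLandscape:
    def test_deterministic_under_seed(self, grid):
        a = generate_landscape(grid, seed=3)
        b = generate_landscape(grid, seed=3)
        for name in a.layer_names:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    def test_lapse_rate_forces_temperature_difference(self, grid):
        # zero noise: temperature = sea_level - lapse * elevation exactly
        env = generate_landscape(
            grid,
            {"temp_noise": 0.0, "sea_level_temp": 25.0, "lapse_rate": 0.0065,
             "elevation_ramp": 1000.0, "elevation_relief": 0.0},
            seed=0,
        )
        t = env["temperature"]
        z = env["elevation"]
        dz = z[0, -1] - z[0, 0]
        assert t[0, 0] - t[0, -1] == pytest.approx(0.0065 * dz)
        assert dz == pytest.approx(1000.0 * (grid.n_cols - 1) / (grid.n_cols - 1))

    def test_zero_noise_flat_terrain_gives_constant_layers(self, grid):
        env = generate_landscape(
            grid,
            {"temp_noise": 0.0, "precip_noise": 0.0, "seasonality_noise": 0.0,
             "elevation_relief": 0.0, "precip_lat_gradient": 0.0},
            seed=0,
        )
        for name in ("temperature", "precip_seasonality", "elevation", "slope"):
            assert np.ptp(env[name]) == 0.0

    def test_negative_lapse_rate_rejected(self, grid):
        with pytest.raises(ValueError):
            generate_landscape(grid, {"lapse_rate": -0.001}, seed=0)

    def test_elevation_nonnegative(self, env):
        assert env["elevation"].min() >= 0.0


class TestTrueSuitability:
    def test_maximum_at_niche_optimum(self, flat_env):
        niche = NicheSpec("s", {"temperature": 24.0}, {"temperature": 2.0}, 0.8)
        suit = true_suitability(flat_env, niche)
        col = np.argmin(np.abs(flat_env["temperature"][0] - 24.0))
        assert suit[0, col] == suit.max()
        assert suit.max() <= 0.8 + 1e-12

    def test_symmetric_around_optimum(self):
        g = GridSpec(1, 3, 0, 1, 0, 3)
        env = EnvStack(g, {"temperature": np.array([[20.0, 25.0, 30.0]]),
                           "elevation": np.zeros((1, 3))})
        niche = NicheSpec("s", {"temperature": 25.0}, {"temperature": 3.0})
        suit = true_suitability(env, niche)
        assert suit[0, 0] == pytest.approx(suit[0, 2])

    def test_matches_per_cell_gaussian_product_oracle(self, env):
        niche = NicheSpec(
            "s",
            {"temperature": 24.0, "precipitation": 1800.0},
            {"temperature": 2.5, "precipitation": 400.0},
            0.85,
        )
        suit = true_suitability(env, niche)
        for i in range(0, env.grid.n_rows, 4):
            for j in range(0, env.grid.n_cols, 5):
                expect = 0.85
                for v, opt in niche.optima.items():
                    b = niche.breadths[v]
                    expect *= math.exp(-((env.layers[v][i, j] - opt) ** 2) / (2 * b * b))
                assert suit[i, j] == pytest.approx(expect, abs=1e-12)

    def test_missing_variable_named_in_error(self, flat_env):
        niche = NicheSpec("s", {"soil_ph": 6.0}, {"soil_ph": 1.0})
        with pytest.raises(KeyError, match="soil_ph"):
            true_suitability(flat_env, niche)


class TestSampleOccurrences:
    def test_all_records_in_single_suitable_cell(self, grid):
        temp = np.full(grid.shape, 0.0)
        temp[4, 7] = 25.0
        env = EnvStack(grid, {"temperature": temp, "elevation": np.zeros(grid.shape)})
        niche = NicheSpec("s", {"temperature": 25.0}, {"temperature": 0.5})
        occ = sample_occurrences(env, niche, 50, seed=1)
        r, c = grid.cell_of(occ.lon, occ.lat)
        assert len(occ) == 50
        assert (r == 4).all() and (c == 7).all()

    def test_counts_track_suitability_at_large_n(self, flat_env, warm_niche):
        occ = sample_occurrences(flat_env, warm_niche, 10_000, seed=3)
        r, c = flat_env.grid.cell_of(occ.lon, occ.lat)
        counts = np.zeros(flat_env.grid.shape)
        np.add.at(counts, (r, c), 1)
        suit = true_suitability(flat_env, warm_niche)
        keep = suit.ravel() > 1e-6
        rho = stats.spearmanr(counts.ravel()[keep], suit.ravel()[keep]).statistic
        assert rho > 0.9

    def test_goodness_of_fit_to_normalized_weights(self):
        # chi-square GOF of empirical cell frequencies vs suitability on 10x10
        g = GridSpec(10, 10, 0, 10, 0, 10)
        rng = np.random.default_rng(5)
        temp = rng.uniform(20, 30, g.shape)
        env = EnvStack(g, {"temperature": temp, "elevation": np.zeros(g.shape)})
        niche = NicheSpec("s", {"temperature": 25.0}, {"temperature": 4.0})
        suit = true_suitability(env, niche)
        n = 100_000
        occ = sample_occurrences(env, niche, n, seed=11)
        r, c = g.cell_of(occ.lon, occ.lat)
        counts = np.zeros(g.shape)
        np.add.at(counts, (r, c), 1)
        expected = suit / suit.sum() * n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=counts.size - 1)
        assert p > 0.01

    def test_all_zero_weights_error(self, flat_env):
        niche = NicheSpec("s", {"temperature": 300.0}, {"temperature": 0.1})
        with pytest.raises(ValueError, match="zero"):
            sample_occurrences(flat_env, niche, 10, seed=0)

    def test_deterministic_under_seed(self, flat_env, warm_niche):
        a = sample_occurrences(flat_env, warm_niche, 200, seed=9)
        b = sample_occurrences(flat_env, warm_niche, 200, seed=9)
        np.testing.assert_array_equal(a.lon, b.lon)
        np.testing.assert_array_equal(a.lat, b.lat)


class TestClimateDelta:
    def test_identity_delta_is_noop(self, env):
        d = ClimateDelta("id", offsets={"temperature": 0.0}, factors={"precipitation": 1.0})
        out = apply_climate_delta(env, d)
        for name in env.layer_names:
            np.testing.assert_array_equal(out.layers[name], env.layers[name])

    def test_uniform_offset_and_factor(self, env):
        d = ClimateDelta("w", offsets={"temperature": 2.0}, factors={"precipitation": 0.8})
        out = apply_climate_delta(env, d)
        np.testing.assert_allclose(out["temperature"], env["temperature"] + 2.0)
        assert out["precipitation"].sum() == pytest.approx(0.8 * env["precipitation"].sum())

    def test_non_climate_layers_untouched_and_input_unmodified(self, env):
        before = env["temperature"].copy()
        d = ClimateDelta("w", offsets={"temperature": 5.0})
        out = apply_climate_delta(env, d)
        np.testing.assert_array_equal(env["temperature"], before)
        for name in set(env.layer_names) - CLIMATE_LAYERS:
            np.testing.assert_array_equal(out.layers[name], env.layers[name])

    def test_delta_on_non_climate_layer_rejected(self):
        with pytest.raises(ValueError, match="non-climate"):
            ClimateDelta("bad", offsets={"elevation": 100.0})

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            ClimateDelta("bad", factors={"precipitation": 0.0})
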