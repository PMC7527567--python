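import numpy as np
import pytest

from ecoland.grids import default_scheme
from ecoland.metrics import label_patches
from ecoland.synth import (
    SyntheticConfig,
    TrueCoefficients,
    generate_dem,
    generate_landscape,
    generate_scenario,
    generate_zones,
    simulate_change,
    write_scenario,
)
from ecoland.grids import read_categorical, read_continuous


class TestConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(proportions={1: 0.5, 9: 0.4})

    def test_minimum_grid_size(self):
        with pytest.raises(ValueError):
            SyntheticConfig(shape=(4, 4))


class TestLandscape:
    def test_same_seed_identical(self):
        cfg = SyntheticConfig(seed=5, shape=(32, 32))
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        assert np.array_equal(a.values, b.values)

    def test_high_cohesion_few_compact_patches(self):
        cfg = SyntheticConfig(seed=2, shape=(64, 64), cohesion=1.0,
                              proportions={1: 0.5, 9: 0.5})
        r = generate_landscape(cfg)
        assert len(label_patches(r)) < 0.05 * 64 * 64

    def test_zero_cohesion_is_independent_multinomial(self):
        p1 = 0.3
        cfg = SyntheticConfig(seed=3, shape=(64, 64), cohesion=0.0,
                              proportions={1: p1, 9: 1 - p1})
        r = generate_landscape(cfg)
        n = 64 * 64
        freq = (r.values == 1).mean()
        assert abs(freq - p1) < 3 * np.sqrt(p1 * (1 - p1) / n)

    def test_realized_proportions_close_to_requested(self):
        cfg = SyntheticConfig(seed=11, shape=(64, 64))
        r = generate_landscape(cfg)
        n = r.values.size
        for code, want in cfg.proportions.items():
            got = (r.values == code).sum() / n
            assert abs(got - want) <= 0.05


class TestDem:
    def test_zero_bumps_flat(self):
        cfg = SyntheticConfig(seed=0, shape=(16, 16), dem_bumps=0)
        assert (generate_dem(cfg).values == 0).all()

    def test_single_bump_peaks_near_center(self):
        cfg = SyntheticConfig(seed=9, shape=(32, 32), dem_bumps=1)
        dem = generate_dem(cfg)
        # the maximum must be the grid cell nearest the bump center, which
        # is strictly inside for this seed; check it is a local maximum
        r, c = np.unravel_index(dem.values.argmax(), dem.values.shape)
        assert dem.values[r, c] == dem.values.max()
        assert dem.values.min() >= 0

    def test_surface_is_smooth(self):
        cfg = SyntheticConfig(seed=4, shape=(64, 64))
        dem = generate_dem(cfg)
        d = np.abs(np.diff(dem.values, axis=0)).mean()
        assert d < cfg.dem_amplitude / 5


class TestZones:
    def test_levels_partition_and_range(self):
        cfg = SyntheticConfig(seed=6, shape=(48, 48), n_zones=13)
        zones, levels = generate_zones(cfg)
        assert set(np.unique(zones.values)) <= set(range(1, 14))
        assert set(np.unique(levels.values)) <= {1, 2, 3, 4, 5}
        # with >= 5 zones every level occurs
        assert set(np.unique(levels.values)) == {1, 2, 3, 4, 5}


class TestSimulateChange:
    def _flat_inputs(self, shape=(48, 48), seed=0):
        cfg = SyntheticConfig(seed=seed, shape=shape, dem_bumps=0)
        rng = np.random.default_rng(seed)
        land = generate_landscape(cfg, rng)
        dem = generate_dem(cfg, rng)
        zones, levels = generate_zones(cfg, rng)
        return cfg, land, dem, levels

    def test_constant_probability_binomial_oracle(self):
        p = 0.3
        cfg, land, dem, levels = self._flat_inputs(seed=8)
        # intercept-only truth: every ecological cell converts w.p. p
        alpha = float(np.log(p / (1 - p)))
        cfg.coefficients = TrueCoefficients(intercept=alpha, slope=0,
                                            elevation=0, distance=0,
                                            level4=0, level5=0)
        t1 = simulate_change(land, dem, levels, cfg,
                             np.random.default_rng(99))
        sch = default_scheme()
        eco = np.isin(land.values, sch.ecological_codes)
        conv = (t1.values != land.values)[eco].mean()
        n = eco.sum()
        assert abs(conv - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_zero_probability_identity(self):
        cfg, land, dem, levels = self._flat_inputs(seed=12)
        cfg.coefficients = TrueCoefficients(intercept=-60, slope=0,
                                            elevation=0, distance=0,
                                            level4=0, level5=0)
        t1 = simulate_change(land, dem, levels, cfg)
        assert np.array_equal(t1.values, land.values)

    def test_conversion_only_touches_ecological_cells(self):
        cfg, land, dem, levels = self._flat_inputs(seed=13)
        t1 = simulate_change(land, dem, levels, cfg)
        sch = default_scheme()
        noneco = ~np.isin(land.values, sch.ecological_codes)
        assert np.array_equal(t1.values[noneco], land.values[noneco])

    def test_near_builtup_cells_convert_more(self):
        cfg, land, dem, levels = self._flat_inputs(shape=(64, 64), seed=14)
        cfg.coefficients = TrueCoefficients(intercept=0.5, slope=0,
                                            elevation=0, distance=-3.0,
                                            level4=0, level5=0)
        from ecoland.logistic import distance_to_builtup
        dist = distance_to_builtup(land).values
        t1 = simulate_change(land, dem, levels, cfg,
                             np.random.default_rng(7))
        sch = default_scheme()
        eco = np.isin(land.values, sch.ecological_codes)
        conv = (t1.values != land.values) & eco
        near = eco & (dist <= np.median(dist[eco]))
        far = eco & (dist > np.median(dist[eco]))
        assert conv[near].mean() > conv[far].mean()

    def test_missing_covariate_layer_raises(self):
        cfg, land, dem, levels = self._flat_inputs()
        with pytest.raises(ValueError, match="covariate"):
            simulate_change(land, None, levels, cfg)


class TestScenario:
    def test_four_dates_co_registered(self, full_scenario):
        b = full_scenario
        assert b.years == [1991, 2000, 2010, 2018]
        first = b.landuse[1991]
        for y in b.years[1:]:
            assert first.co_registered_with(b.landuse[y])
            assert b.landuse[y].year == y

    def test_seed_changes_values_not_shapes(self):
        a = generate_scenario(SyntheticConfig(seed=1, shape=(32, 32)))
        b = generate_scenario(SyntheticConfig(seed=2, shape=(32, 32)))
        assert a.landuse[2018].shape == b.landuse[2018].shape
        assert not np.array_equal(a.landuse[2018].values,
                                  b.landuse[2018].values)

    def test_full_determinism_under_seed(self):
        a = generate_scenario(SyntheticConfig(seed=21, shape=(32, 32)))
        b = generate_scenario(SyntheticConfig(seed=21, shape=(32, 32)))
        for y in a.years:
            assert np.array_equal(a.landuse[y].values, b.landuse[y].values)
        assert np.array_equal(a.dem.values, b.dem.values)
        assert np.array_equal(a.levels.values, b.levels.values)

    def test_transition_frequency_matches_generating_probability(self):
        """Realized eco->built conversions agree with the mean of the
        generating per-cell probabilities to within binomial error."""
        from scipy.stats import logistic as slog
        from ecoland.logistic import compute_slope, distance_to_builtup
        cfg = SyntheticConfig(seed=31, shape=(96, 96), dates=(1991, 2000))
        b = generate_scenario(cfg)
        sch = default_scheme()
        k = cfg.coefficients
        lv = b.levels.values
        z = (k.intercept + k.slope * compute_slope(b.dem).values
             + k.elevation * b.dem.values
             + k.distance * distance_to_builtup(b.landuse[1991]).values
             + k.level4 * (lv == 4) + k.level5 * (lv == 5))
        p = slog.cdf(z)
        eco = np.isin(b.landuse[1991].values, sch.ecological_codes)
        expected = p[eco].mean()
        realized = (b.landuse[2000].values != b.landuse[1991].values)[eco].mean()
        n = eco.sum()
        spread = np.sqrt((p[eco] * (1 - p[eco])).sum()) / n
        assert abs(realized - expected) <= 4 * spread

    def test_write_scenario_round_trips(self, tmp_path, small_scenario):
        out = write_scenario(small_scenario, tmp_path / "scn")
        assert (out / "manifest.json").exists()
        sch = default_scheme()
        back = read_categorical(out / "landuse_1991.asc", sch)
        assert np.array_equal(back.values, small_scenario.landuse[1991].values)
        dem = read_continuous(out / "dem.asc")
        assert np.allclose(dem.values, small_scenario.dem.values)
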