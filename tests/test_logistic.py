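import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from ecoland.grids import ContinuousRaster, RasterError, default_scheme
from ecoland.logistic import (
    SampleSet,
    SeparationError,
    TransformCoefficients,
    annual_growth_rate,
    build_covariates,
    classify_probability,
    compute_slope,
    confusion_stats,
    distance_to_builtup,
    draw_samples,
    evaluate_transform_probability,
    fit_logistic,
    growth_level,
    growth_rate_levels,
    predict_probability_map,
    validate,
)

from conftest import make_raster


def _dem(values, cell_size=30.0):
    return ContinuousRaster(np.asarray(values, float), None, cell_size,
                            (0.0, 0.0), units="m")


class TestSlope:
    def test_flat_dem_zero_slope(self):
        s = compute_slope(_dem(np.zeros((8, 8))))
        assert np.allclose(s.values, 0)
        assert s.units == "degrees"

    def test_inclined_plane_arctan_gradient(self):
        g = 0.1
        x = np.arange(10) * 30.0 * g
        dem = _dem(np.tile(x, (10, 1)))
        s = compute_slope(dem)
        assert np.allclose(s.values[1:-1, 1:-1], np.degrees(np.arctan(g)))

    def test_isotropy_under_rotation(self):
        g = 0.05
        x = np.arange(12) * 30.0 * g
        a = compute_slope(_dem(np.tile(x, (12, 1)))).values[2:-2, 2:-2]
        b = compute_slope(_dem(np.tile(x, (12, 1)).T)).values[2:-2, 2:-2]
        assert np.allclose(a, b)

    def test_degenerate_dem_rejected(self):
        with pytest.raises(RasterError):
            compute_slope(_dem(np.zeros((1, 9))))


class TestDistance:
    def test_distances_from_single_builtup_cell(self):
        v = np.ones((5, 5), dtype=int)
        v[2, 2] = 9
        d = distance_to_builtup(make_raster(v))
        assert d.values[2, 2] == 0.0
        assert d.values[2, 3] == pytest.approx(0.03)       # 4-neighbor
        assert d.values[3, 3] == pytest.approx(0.03 * np.sqrt(2))
        assert d.units == "km"

    def test_no_builtup_raises(self):
        with pytest.raises(RasterError, match="built-up"):
            distance_to_builtup(make_raster(np.ones((4, 4), dtype=int)))


class TestGrowthLevels:
    def test_doubling_over_27_years_is_level_1(self):
        r = annual_growth_rate(1.0, 2.0, 27)
        assert r == pytest.approx(2 ** (1 / 27) - 1)
        assert r == pytest.approx(0.026, abs=5e-4)
        assert growth_level(r) == 1

    @pytest.mark.parametrize("rate,level", [
        (0.0, 1), (0.05, 1), (0.0501, 2), (0.10, 2), (0.12, 3),
        (0.20, 3), (0.25, 4), (0.35, 4), (0.40, 5), (-0.02, 1),
    ])
    def test_bin_lookup(self, rate, level):
        assert growth_level(rate) == level

    def test_arithmetic_variant(self):
        assert annual_growth_rate(2.0, 4.0, 10, "arithmetic") == pytest.approx(0.1)

    def test_zero_start_area_raises(self):
        with pytest.raises(ValueError):
            annual_growth_rate(0.0, 5.0, 10)

    def test_levels_broadcast_per_zone(self):
        cols = np.arange(8)[None, :] * np.ones((8, 1), dtype=int)
        t0 = make_raster(np.where((cols == 0) | (cols == 4), 9, 1))
        t1 = make_raster(np.where(cols % 2 == 0, 9, 1))  # doubles in each zone
        zones = make_raster(np.where(cols < 4, 1, 2))
        lv = growth_rate_levels(t0, t1, 5.0, zones)
        want = growth_level(2 ** (1 / 5) - 1)
        assert (lv.values == want).all()

    def test_zone_without_builtup_at_t0_raises(self):
        t0 = make_raster(np.ones((6, 6), dtype=int))
        t0.values[0, 0] = 9
        zones = make_raster(np.where(np.arange(6)[None, :] < 3, 1, 2)
                            * np.ones((6, 6), dtype=int))
        with pytest.raises(ValueError, match="zero built-up"):
            growth_rate_levels(t0, t0, 5.0, zones)


class TestEquationEvaluation:
    def test_all_zero_covariates(self):
        assert evaluate_transform_probability(0, 0, 0, 0, 0) == pytest.approx(
            0.7012, abs=5e-5)

    def test_worked_point(self):
        assert evaluate_transform_probability(10, 100, 1, 1, 0) == pytest.approx(
            0.0737, abs=5e-5)

    def test_equals_one_minus_sigmoid_identity(self, rng):
        A, B, C = rng.normal(size=(3, 200))
        D = rng.integers(0, 2, 200)
        E = (1 - D) * rng.integers(0, 2, 200)
        k = TransformCoefficients()
        z = (k.slope * A + k.elevation * B + k.distance * C
             + k.level4 * D + k.level5 * E + k.intercept)
        p = evaluate_transform_probability(A, B, C, D, E)
        assert np.allclose(p, 1 - stats.logistic.cdf(z), atol=1e-14)
        assert np.allclose(p, stats.logistic.cdf(-z), atol=1e-14)

    def test_monotone_decreasing_in_distance(self):
        c = np.linspace(0, 10, 50)
        p = evaluate_transform_probability(5, 50, c, 0, 0)
        assert (np.diff(p) < 0).all()


def _toy_samples(n=4000, seed=0, beta=(0.8, -1.2), alpha=0.3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "slope": rng.normal(size=n),
        "elevation": rng.normal(size=n),
    })
    z = alpha + beta[0] * X["slope"] + beta[1] * X["elevation"]
    y = np.asarray(rng.random(n) < stats.logistic.cdf(z), dtype=int)
    return SampleSet(X=X, y=y, rows=np.zeros(n, int),
                     cols=np.zeros(n, int), seed=seed)


class TestFitting:
    def test_intercept_only_balanced_outcome(self):
        n = 1000
        X = pd.DataFrame({"slope": np.zeros(n), "elevation": np.ones(n)})
        y = np.array([0, 1] * (n // 2))
        s = SampleSet(X=X, y=y, rows=np.zeros(n, int), cols=np.zeros(n, int))
        fit = fit_logistic(s, variables=[])
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.included == []

    def test_recovers_known_coefficients(self):
        s = _toy_samples()
        fit = fit_logistic(s)
        assert abs(fit.coefficients["slope"] - 0.8) < 3 * fit.std_errors["slope"]
        assert abs(fit.coefficients["elevation"] + 1.2) < 3 * fit.std_errors["elevation"]
        assert abs(fit.intercept - 0.3) < 3 * fit.std_errors["intercept"]

    def test_neg2ll_matches_direct_evaluation(self):
        s = _toy_samples(seed=5)
        fit = fit_logistic(s)
        p = fit.predict_persistence(s.X)
        direct = -2 * np.sum(s.y * np.log(p) + (1 - s.y) * np.log(1 - p))
        assert fit.neg2ll == pytest.approx(direct, rel=1e-9)
        assert fit.neg2ll <= -2 * _null_ll(s.y) + 1e-9

    def test_agrees_with_generic_numerical_maximizer(self):
        """IRLS estimates match a direct scipy maximization of the
        log-likelihood to 1e-6."""
        s = _toy_samples(n=600, seed=9)
        fit = fit_logistic(s)
        X = np.column_stack([np.ones(s.n), s.X["slope"], s.X["elevation"]])

        def nll(b):
            z = X @ b
            return np.sum(np.logaddexp(0, z) - s.y * z)

        res = optimize.minimize(nll, np.zeros(3), method="BFGS",
                                options={"gtol": 1e-10})
        got = np.array([fit.intercept, fit.coefficients["slope"],
                        fit.coefficients["elevation"]])
        assert np.allclose(got, res.x, atol=1e-6)

    def test_order_invariance(self):
        s = _toy_samples(n=800, seed=3)
        perm = np.random.default_rng(0).permutation(s.n)
        s2 = SampleSet(X=s.X.iloc[perm].reset_index(drop=True), y=s.y[perm],
                       rows=s.rows[perm], cols=s.cols[perm])
        f1, f2 = fit_logistic(s), fit_logistic(s2)
        for k in f1.coefficients:
            assert f1.coefficients[k] == pytest.approx(f2.coefficients[k],
                                                       abs=1e-9)

    def test_stepwise_keeps_informative_drops_noise(self):
        rng = np.random.default_rng(17)
        n = 4000
        X = pd.DataFrame({
            "slope": rng.normal(size=n),
            "elevation": rng.normal(size=n),   # pure noise
        })
        z = 1.5 * X["slope"] - 0.5
        y = np.asarray(rng.random(n) < stats.logistic.cdf(z), dtype=int)
        s = SampleSet(X=X, y=y, rows=np.zeros(n, int),
                      cols=np.zeros(n, int))
        fit = fit_logistic(s, stepwise=True)
        assert "slope" in fit.included
        assert "elevation" not in fit.included

    def test_single_class_outcome_rejected(self):
        s = _toy_samples(n=100)
        s.y[:] = 1
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(s)

    def test_complete_separation_names_variable(self):
        n = 200
        x = np.concatenate([np.linspace(-2, -1, n // 2),
                            np.linspace(1, 2, n // 2)])
        X = pd.DataFrame({"slope": x, "elevation": np.random.default_rng(0).normal(size=n)})
        y = (x > 0).astype(int)
        s = SampleSet(X=X, y=y, rows=np.zeros(n, int), cols=np.zeros(n, int))
        with pytest.raises(SeparationError, match="slope"):
            fit_logistic(s)


def _null_ll(y):
    p = y.mean()
    return np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


class TestSampling:
    @pytest.fixture
    def scenario_stack(self, small_scenario, scheme):
        b = small_scenario
        return b, build_covariates(b.dem, b.landuse[1991], b.levels)

    def test_same_seed_identical_samples(self, scenario_stack, scheme):
        b, stack = scenario_stack
        a = draw_samples(b.landuse[1991], b.landuse[2000], stack, scheme,
                         500, seed=4)
        c = draw_samples(b.landuse[1991], b.landuse[2000], stack, scheme,
                         500, seed=4)
        assert np.array_equal(a.rows, c.rows)
        assert a.X.equals(c.X)

    def test_exhaustive_sample_covers_all_eco_cells(self, scenario_stack, scheme):
        b, stack = scenario_stack
        eco = np.isin(b.landuse[1991].values, scheme.ecological_codes)
        s = draw_samples(b.landuse[1991], b.landuse[2000], stack, scheme,
                         int(eco.sum()), seed=0)
        got = set(zip(s.rows.tolist(), s.cols.tolist()))
        want = set(zip(*[a.tolist() for a in np.nonzero(eco)]))
        assert got == want

    def test_oversampling_rejected(self, scenario_stack, scheme):
        b, stack = scenario_stack
        with pytest.raises(ValueError, match="samples"):
            draw_samples(b.landuse[1991], b.landuse[2000], stack, scheme,
                         10**7, seed=0)

    def test_prevalence_close_to_map_persistence(self, scenario_stack, scheme):
        b, stack = scenario_stack
        eco0 = np.isin(b.landuse[1991].values, scheme.ecological_codes)
        eco1 = np.isin(b.landuse[2000].values, scheme.ecological_codes)
        p = eco1[eco0].mean()
        n = 1000
        s = draw_samples(b.landuse[1991], b.landuse[2000], stack, scheme,
                         n, seed=2)
        assert abs(s.y.mean() - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestValidation:
    def test_perfect_diagonal(self):
        v = confusion_stats([[50, 0], [0, 50]])
        assert v.overall_accuracy == 100.0
        assert v.kappa == pytest.approx(1.0)

    def test_uniform_matrix_chance_agreement(self):
        v = confusion_stats([[25, 25], [25, 25]])
        assert v.kappa == pytest.approx(0.0)

    def test_validate_against_known_probabilities(self):
        # deterministic coefficients, threshold at 0.5
        n = 100
        X = pd.DataFrame({
            "slope": np.zeros(n), "elevation": np.zeros(n),
            "distance": np.linspace(0, 5, n),
            "level2": 0.0, "level3": 0.0, "level4": 0.0, "level5": 0.0,
        })
        y = np.ones(n, dtype=int)  # all persist
        s = SampleSet(X=X, y=y, rows=np.zeros(n, int), cols=np.zeros(n, int))
        v = validate(TransformCoefficients(), s)
        p = evaluate_transform_probability(0, 0, X["distance"], 0, 0)
        assert v.matrix[0, 1] == (p > 0.5).sum()

    def test_empty_holdout_rejected(self):
        s = SampleSet(X=pd.DataFrame({"slope": []}), y=np.array([], int),
                      rows=np.array([], int), cols=np.array([], int))
        with pytest.raises(ValueError):
            validate(TransformCoefficients(), s)


class TestProbabilityMap:
    @pytest.mark.parametrize("p,level", [
        (0.05, 1), (0.1, 1), (0.30, 2), (0.31, 3), (0.45, 3),
        (0.46, 4), (0.65, 4), (0.66, 5),
    ])
    def test_level_bins(self, p, level):
        assert classify_probability(np.array([p]))[0] == level

    def test_constant_covariates_constant_map(self, scheme):
        v = np.ones((10, 10), dtype=int)
        v[0, 0] = 9
        land = make_raster(v)
        flat = ContinuousRaster(np.zeros((10, 10)), None, 30.0, (0.0, 0.0))
        from ecoland.logistic import CovariateStack
        stack = CovariateStack(
            slope=flat,
            elevation=flat,
            distance=ContinuousRaster(np.zeros((10, 10)), None, 30.0,
                                      (0.0, 0.0), units="km"),
            levels=make_raster(np.ones((10, 10), dtype=int)),
        )
        prob, levels, classprob = predict_probability_map(stack, land, scheme)
        eco = land.values == 1
        assert np.allclose(prob.values[eco],
                           evaluate_transform_probability(0, 0, 0, 0, 0))
        assert prob.mask[0, 0]  # built-up cell masked out

    def test_level_map_partitions_all_ecological_cells(self, small_scenario,
                                                       scheme):
        b = small_scenario
        stack = build_covariates(b.dem, b.landuse[1991], b.levels)
        prob, levels, _ = predict_probability_map(stack, b.landuse[2000],
                                                  scheme)
        eco = np.isin(b.landuse[2000].values, scheme.ecological_codes)
        assert set(np.unique(levels.values[eco])) <= {1, 2, 3, 4, 5}
        assert (levels.values[eco] >= 1).all()
        assert (~levels.mask == eco).all()
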