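"""Variogram models, ML fitting, kriging and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from fbgeo import geostat
from fbgeo.geostat import (
    GeostatError,
    VariogramModel,
    effective_range,
    empirical_variogram,
    fit_variogram_ml,
    loo_cross_validation,
    map_grid,
    matern_semivariance,
    ordinary_kriging,
)
from fbgeo.synth import simulate_field

from conftest import make_samples

MODEL = VariogramModel(nugget=0.2, partial_sill=0.8, range_param=28.04, nu=0.5)


class TestSemivariance:
    def test_zero_at_origin_and_nugget_jump(self):
        assert matern_semivariance(0.0, MODEL) == 0.0
        assert matern_semivariance(1e-9, MODEL) == pytest.approx(MODEL.nugget, rel=1e-3)

    @pytest.mark.parametrize("nu", [0.5])
    def test_exponential_special_case(self, nu):
        m = VariogramModel(nugget=0.3, partial_sill=0.7, range_param=20.0, nu=nu)
        h = np.linspace(0.01, 200, 300)
        expected = 0.3 + 0.7 * (1 - np.exp(-h / 20.0))
        np.testing.assert_allclose(matern_semivariance(h, m), expected, rtol=1e-12)

    @pytest.mark.parametrize("nu", [0.5, 1.5, 2.5, 1.0])
    def test_sill_limit(self, nu):
        m = VariogramModel(nugget=0.2, partial_sill=0.8, range_param=10.0, nu=nu)
        assert matern_semivariance(50 * m.range_param, m) == pytest.approx(1.0, abs=1e-6)


class TestEffectiveRange:
    def test_exponential_practical_range(self):
        m = VariogramModel(nugget=0.0, partial_sill=1.0, range_param=28.04, nu=0.5)
        # 95% level of the exponential model sits at -ln(0.05)*a (~3a)
        assert effective_range(m) == pytest.approx(-np.log(0.05) * 28.04, rel=1e-6)
        assert effective_range(m) == pytest.approx(84.0, rel=0.01)

    def test_pure_nugget_undefined(self):
        m = VariogramModel(nugget=1.0, partial_sill=0.0, range_param=10.0, nu=0.5)
        assert effective_range(m) is None

    def test_monotone_in_range_param(self):
        ranges = [
            effective_range(VariogramModel(0.1, 0.9, a, 1.5)) for a in (5, 10, 20, 40)
        ]
        assert all(np.diff(ranges) > 0)


class TestEmpiricalVariogram:
    def test_two_point_semivariance(self):
        samples = make_samples(np.array([[0.0, 0.0], [10.0, 0.0]]), np.array([1.0, 3.0]))
        ev = empirical_variogram(samples, lag_width=5.0, max_dist=20.0)
        assert len(ev.lag_centers) == 1
        assert ev.semivariances[0] == pytest.approx(2.0)
        assert ev.pair_counts[0] == 1

    def test_constant_field_zero(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 100, (30, 2))
        ev = empirical_variogram(make_samples(xy, np.full(30, 5.0)))
        assert np.all(ev.semivariances == 0.0)

    def test_beyond_max_dist_errors(self):
        samples = make_samples(np.array([[0.0, 0.0], [100.0, 0.0]]), np.array([1.0, 2.0]))
        with pytest.raises(GeostatError):
            empirical_variogram(samples, lag_width=5.0, max_dist=10.0)

    def test_tracks_planted_exponential_model(self, uniform_sites_500):
        rng = np.random.default_rng(8)
        z = simulate_field(uniform_sites_500, 28.04, 0.5, 0.2, 0.8, rng)
        ev = empirical_variogram(make_samples(uniform_sites_500, z), lag_width=10.0)
        model_gamma = matern_semivariance(ev.lag_centers, MODEL)
        mid = (ev.lag_centers > 10) & (ev.lag_centers < 100)
        rel = np.abs(ev.semivariances[mid] - model_gamma[mid]) / model_gamma[mid]
        assert np.median(rel) < 0.25


class TestMlFit:
    def test_white_noise_flags_pure_nugget(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 300, (200, 2))
        z = rng.standard_normal(200)
        m = fit_variogram_ml(make_samples(xy, z), nu_candidates=(0.5,))
        assert m.partial_sill < 0.05 * np.var(z)
        assert m.pure_nugget

    def test_smoothness_selected_on_pure_matern_fields(self, uniform_sites_500):
        # near-origin behavior identifies nu on irregular layouts; a nugget
        # would be confounded with smoothness, so the planted field has none
        cache = {}
        wins = 0
        n_rep = 50
        for s in range(n_rep):
            rng = np.random.default_rng(9_000 + s)
            z = simulate_field(uniform_sites_500, 28.04, 0.5, 0.0, 1.0, rng, cache)
            m = fit_variogram_ml(make_samples(uniform_sites_500, z))
            wins += m.nu == 0.5
        assert wins >= 0.8 * n_rep

    def test_too_few_samples(self):
        with pytest.raises(GeostatError):
            fit_variogram_ml(make_samples(np.zeros((2, 2)), np.array([0.0, 1.0])))


class TestOrdinaryKriging:
    def test_single_neighbor_copies_value(self):
        samples = make_samples(np.array([[0.0, 0.0], [50.0, 50.0]]), np.array([2.0, 7.0]))
        pred = ordinary_kriging(MODEL, samples, np.array([[1.0, 1.0]]), neighborhood_size=1)
        assert pred["estimate"][0] == pytest.approx(2.0)

    def test_pure_nugget_gives_neighborhood_mean(self):
        m = VariogramModel(nugget=1.0, partial_sill=0.0, range_param=10.0, nu=0.5)
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 50, (12, 2))
        z = rng.standard_normal(12)
        pred = ordinary_kriging(m, make_samples(xy, z), np.array([[25.0, 25.0]]),
                                neighborhood_size=None)
        assert pred["estimate"][0] == pytest.approx(z.mean(), abs=1e-10)

    def test_exact_interpolation_without_nugget(self):
        m = VariogramModel(nugget=0.0, partial_sill=1.0, range_param=30.0, nu=0.5)
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 100, (15, 2))
        z = rng.standard_normal(15)
        pred = ordinary_kriging(m, make_samples(xy, z), xy[3][None, :], neighborhood_size=None)
        assert pred["estimate"][0] == pytest.approx(z[3], abs=1e-8)
        assert pred["kriging_variance"][0] == pytest.approx(0.0, abs=1e-8)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(0, 200, (80, 2))
        z = rng.standard_normal(80)
        targets = rng.uniform(0, 200, (20, 2))
        _, _, wsums = geostat._ok_solve(MODEL, xy, z, targets, 16)
        np.testing.assert_allclose(wsums, 1.0, atol=1e-10)

    def test_matches_gls_oracle_small_instances(self):
        # with all points in the neighborhood, ordinary kriging equals the
        # generalized-least-squares predictor built from the full covariance
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = rng.integers(4, 9)
            xy = rng.uniform(0, 100, (n, 2))
            z = rng.standard_normal(n)
            x0 = rng.uniform(0, 100, 2)
            C = MODEL.covariance(cdist(xy, xy))
            np.fill_diagonal(C, MODEL.sill)
            c0 = MODEL.covariance(cdist([x0], xy)[0])
            Ci = np.linalg.inv(C)
            one = np.ones(n)
            mu = (one @ Ci @ z) / (one @ Ci @ one)
            gls = mu + c0 @ Ci @ (z - mu * one)
            pred = ordinary_kriging(MODEL, make_samples(xy, z), x0[None, :],
                                    neighborhood_size=None)
            assert pred["estimate"][0] == pytest.approx(gls, abs=1e-8)


class TestLooCv:
    def test_constant_field_zero_errors(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(0, 100, (20, 2))
        samples = make_samples(xy, np.full(20, 3.0))
        cv = loo_cross_validation(MODEL, samples)
        np.testing.assert_allclose(cv.table["predicted"], 3.0, atol=1e-10)
        np.testing.assert_allclose(cv.table["sspe"], 0.0, atol=1e-12)

    def test_inflated_sill_quarters_mean_sspe(self):
        inflated = VariogramModel(nugget=0.8, partial_sill=3.2, range_param=28.04, nu=0.5)
        rng = np.random.default_rng(10)
        xy = rng.uniform(0, 400, (150, 2))
        cache = {}
        ratios = []
        for s in range(10):
            r = np.random.default_rng(s)
            z = simulate_field(xy, 28.04, 0.5, 0.2, 0.8, r, cache)
            samples = make_samples(xy, z)
            ratios.append(loo_cross_validation(inflated, samples).mean_sspe)
        assert np.mean(ratios) == pytest.approx(0.25, abs=0.08)


class TestMapGrid:
    def test_node_on_sample_without_nugget(self):
        m = VariogramModel(nugget=0.0, partial_sill=1.0, range_param=30.0, nu=0.5)
        xy = np.array([[0.0, 0.0], [16.0, 0.0], [0.0, 16.0], [16.0, 16.0]])
        z = np.array([1.0, 2.0, 3.0, 4.0])
        grid = map_grid(m, make_samples(xy, z), bbox=(0, 0, 16, 16), resolution_km=16.0)
        at_origin = grid[(grid["x_km"] == 0) & (grid["y_km"] == 0)]
        assert at_origin["estimate"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_resolution_halving_quadruples_nodes(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 64, (10, 2))
        samples = make_samples(xy, rng.standard_normal(10))
        g1 = map_grid(MODEL, samples, bbox=(0, 0, 64, 64), resolution_km=16.0)
        g2 = map_grid(MODEL, samples, bbox=(0, 0, 64, 64), resolution_km=8.0)
        assert len(g2) / len(g1) == pytest.approx(
            ((64 / 8 + 1) / (64 / 16 + 1)) ** 2
        )

    def test_national_scale_smoke(self):
        # ~2,000 sites kriged onto a 16-km national grid completes quickly
        rng = np.random.default_rng(12)
        xy = rng.uniform(0, 750, (2000, 2))
        z = rng.standard_normal(2000)
        grid = map_grid(MODEL, make_samples(xy, z), resolution_km=16.0,
                        neighborhood_size=32)
        assert len(grid) > 2000
        assert np.all(grid["kriging_variance"] >= 0)
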