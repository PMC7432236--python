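"""Lognormal ordinary kriging: variogram fitting, prediction, CV, moments."""

import numpy as np
import pytest

from rfmap.exceptions import (
    DegenerateFieldError,
    InsufficientDataError,
    InvalidVarianceError,
    NoNeighborError,
)
from rfmap.kriging import (
    OrdinaryKriging,
    VariogramModel,
    backtransform,
    fit_variogram,
    krige_point,
    loo_cv,
)
from rfmap.scene import simulate_gaussian_field


def _scatter(n, extent, seed):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, extent, (n, 2)), rng


class TestVariogram:
    def test_iid_data_shows_pure_nugget(self):
        coords, rng = _scatter(2000, 1400, 0)
        z = rng.normal(0.0, 0.7, 2000)  # no spatial correlation
        vg = fit_variogram(coords, z)
        assert vg.partial_sill < 0.25 * vg.sill

    def test_simulated_range_recovered(self):
        # single-replicate check; the multi-replicate version lives in the
        # acceptance suite
        coords, rng = _scatter(1000, 2000, 3)
        z = simulate_gaussian_field(coords, 0.5, 300.0, rng)
        vg = fit_variogram(coords, z)
        assert vg.range_m == pytest.approx(300.0, rel=0.5)
        assert vg.sill == pytest.approx(0.5, rel=0.6)

    def test_constant_field_is_degenerate(self):
        coords, _ = _scatter(100, 1000, 1)
        with pytest.raises(DegenerateFieldError):
            fit_variogram(coords, np.zeros(100))

    def test_too_few_points_rejected(self):
        coords, rng = _scatter(10, 1000, 2)
        with pytest.raises(InsufficientDataError):
            fit_variogram(coords, rng.normal(size=10))

    def test_semivariance_at_zero_is_nugget_and_nondecreasing(self):
        vg = VariogramModel("exponential", 0.1, 0.4, 300.0)
        h = np.linspace(0, 2000, 200)
        g = vg.semivariance(h)
        assert g[0] == pytest.approx(0.1)
        assert (np.diff(g) >= -1e-12).all()

    @pytest.mark.parametrize("family", ["exponential", "spherical", "gaussian"])
    def test_practical_range_convention(self, family):
        vg = VariogramModel(family, 0.0, 1.0, 300.0)
        assert vg.semivariance(np.array([300.0]))[0] >= 0.95 - 1e-9


class TestKrigePoint:
    VG = VariogramModel("exponential", 0.0, 0.5, 300.0)

    def test_exact_interpolation_at_sample_with_zero_nugget(self):
        coords, rng = _scatter(50, 500, 4)
        vals = rng.normal(size=50)
        z, s2 = krige_point(coords, vals, tuple(coords[7]), self.VG)
        assert z == pytest.approx(vals[7], abs=1e-9)
        assert s2 == pytest.approx(0.0, abs=1e-9)

    def test_single_neighbor_closed_form(self):
        # one conditioning point: weight 1, variance 2 gamma(d) - gamma(0)
        vg = VariogramModel("exponential", 0.1, 0.4, 300.0)
        coords = np.array([[0.0, 0.0]])
        vals = np.array([1.7])
        d = 120.0
        z, s2 = krige_point(coords, vals, (d, 0.0), vg, neighborhood_radius=1e9)
        g = float(vg.semivariance(np.array([d]))[0])
        assert z == pytest.approx(1.7)
        assert s2 == pytest.approx(2 * g - vg.nugget)

    def test_three_point_system_matches_dense_solve(self):
        # independent hand-built ordinary-kriging solve
        vg = VariogramModel("spherical", 0.05, 0.45, 250.0)
        coords = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 150.0]])
        vals = np.array([1.0, 2.0, 0.5])
        target = (40.0, 40.0)

        n = 3
        A = np.zeros((n + 1, n + 1))
        for i in range(n):
            for j in range(n):
                h = np.hypot(*(coords[i] - coords[j]))
                A[i, j] = vg.nugget + vg.partial_sill * float(
                    vg.structure(np.array([h]))[0]
                )
        A[:n, n] = A[n, :n] = 1.0
        b = np.zeros(n + 1)
        for i in range(n):
            h = np.hypot(coords[i, 0] - target[0], coords[i, 1] - target[1])
            b[i] = float(vg.semivariance(np.array([h]))[0])
        b[n] = 1.0
        sol = np.linalg.solve(A, b)
        z_exp = float(sol[:n] @ vals)
        s2_exp = float(sol[:n] @ b[:n] + sol[n])

        z, s2 = krige_point(coords, vals, target, vg, neighborhood_radius=1e9)
        assert z == pytest.approx(z_exp, abs=1e-10)
        assert s2 == pytest.approx(s2_exp, abs=1e-10)

    def test_weights_sum_to_one_via_constant_field(self):
        # the unbiasedness constraint means any constant field is
        # reproduced exactly at every target
        coords, _ = _scatter(60, 800, 5)
        vals = np.full(60, 3.21)
        for target in [(12.0, 700.0), (400.0, 400.0), (790.0, 5.0)]:
            z, _ = krige_point(coords, vals, target, self.VG,
                               neighborhood_radius=1e9)
            assert z == pytest.approx(3.21, abs=1e-9)

    def test_no_neighbor_raises(self):
        coords = np.array([[0.0, 0.0]])
        with pytest.raises(NoNeighborError):
            krige_point(coords, np.array([1.0]), (5000.0, 5000.0), self.VG,
                        neighborhood_radius=100.0)

    def test_duplicate_points_deduplicated(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0]])
        vals = np.array([1.0, 3.0, 2.0])
        with pytest.warns(UserWarning, match="dedup"):
            z, _ = krige_point(coords, vals, (50.0, 0.0), self.VG,
                               neighborhood_radius=1e9)
        assert np.isfinite(z)


class TestBacktransform:
    def test_identity_and_doubling_cases(self):
        assert backtransform(0.0, 0.0) == pytest.approx((1.0, 0.0))
        assert backtransform(np.log(2.0), 0.0) == pytest.approx((2.0, 0.0))

    def test_matches_lognormal_monte_carlo_moments(self, rng):
        mu, s2 = 0.3, 0.4
        z_lin, s2_lin = backtransform(mu, s2)
        draws = rng.lognormal(mu, np.sqrt(s2), 10**6)
        assert z_lin == pytest.approx(draws.mean(), rel=5e-3)
        assert s2_lin == pytest.approx(draws.var(), rel=2e-2)

    def test_negative_variance_rejected(self):
        with pytest.raises(InvalidVarianceError):
            backtransform(0.0, -0.1)


class TestGridAndModel:
    def test_constant_field_with_jitter_reproduced_on_grid(self, rng):
        x = rng.uniform(0, 1000, 80)
        y = rng.uniform(0, 1000, 80)
        field = np.exp(rng.normal(np.log(0.5), 1e-6, 80))
        ok = OrdinaryKriging(
            x, y, field,
        ).fit(VariogramModel("exponential", 0.0, 1e-12, 300.0))
        grid = np.column_stack(
            [rng.uniform(0, 1000, 20), rng.uniform(0, 1000, 20)]
        )
        est = ok.predict(grid)
        assert est["z_lin"].to_numpy() == pytest.approx(
            np.full(20, 0.5), rel=1e-4
        )

    def test_cell_coinciding_with_measurement_reproduces_it(self, rng):
        x = rng.uniform(0, 500, 40)
        y = rng.uniform(0, 500, 40)
        field = np.exp(rng.normal(0, 0.5, 40))
        res = OrdinaryKriging(x, y, field).fit(
            VariogramModel("exponential", 0.0, 0.5, 200.0)
        )
        est = res.predict(np.array([[x[3], y[3]]]))
        assert est["z_log"].iloc[0] == pytest.approx(np.log(field[3]), abs=1e-9)

    def test_local_radius_covering_scene_equals_global(self, rng):
        x = rng.uniform(0, 400, 50)
        y = rng.uniform(0, 400, 50)
        field = np.exp(rng.normal(0, 0.5, 50))
        vg = VariogramModel("exponential", 0.02, 0.5, 50.0)
        res = OrdinaryKriging(x, y, field).fit(vg)
        targets = np.column_stack(
            [rng.uniform(0, 400, 10), rng.uniform(0, 400, 10)]
        )
        a = res.predict(targets, neighborhood_radius=600.0)  # > diameter
        b = res.predict(targets, neighborhood_radius=1e12)
        np.testing.assert_allclose(a["z_log"], b["z_log"], atol=1e-12)
        np.testing.assert_allclose(a["s2_log"], b["s2_log"], atol=1e-12)

    def test_no_neighbor_cells_fall_back_flagged(self, rng):
        x = rng.uniform(0, 100, 35)
        y = rng.uniform(0, 100, 35)
        field = np.exp(rng.normal(0, 0.3, 35))
        vg = VariogramModel("exponential", 0.0, 0.3, 50.0)
        res = OrdinaryKriging(x, y, field).fit(vg)
        est = res.predict(np.array([[5000.0, 5000.0], [50.0, 50.0]]))
        assert bool(est["no_neighbor"].iloc[0])
        assert est["z_log"].iloc[0] == pytest.approx(res.global_mean_log)
        assert est["s2_log"].iloc[0] == pytest.approx(vg.sill)
        assert not bool(est["no_neighbor"].iloc[1])

    def test_full_scene_grid_rmse_beats_prior_spread(self):
        # with dense sampling the kriged grid is far closer to the known
        # simulated field than the field's own standard deviation
        from rfmap.kriging import OrdinaryKriging
        from rfmap.scene import SceneConfig, gen_district, gen_drive_test

        cfg = SceneConfig(seed=21)
        scene = gen_district(cfg)
        drive, truth = gen_drive_test(cfg, 1000, truth_at=scene.grid.centers())
        res = OrdinaryKriging.from_dataframe(drive).fit()
        est = res.predict(scene.grid.centers())
        rmse = float(np.sqrt(np.mean((est["z_log"].to_numpy() - truth) ** 2)))
        assert rmse < np.sqrt(cfg.log_variance)


class TestLooCv:
    def test_zero_exclusion_is_plain_loo(self, rng):
        coords = rng.uniform(0, 500, (40, 2))
        vals = rng.normal(0, 0.5, 40)
        vg = VariogramModel("exponential", 0.01, 0.5, 200.0)
        cv = loo_cv(coords, vals, vg, exclusion_radius=0.0)
        assert len(cv.table) == 40
        assert cv.n_unpredictable == 0
        assert cv.rmse >= 0

    def test_near_constant_field_has_near_zero_rmse(self, rng):
        coords = rng.uniform(0, 500, (30, 2))
        vals = np.full(30, 1.0) + rng.normal(0, 1e-9, 30)
        vg = VariogramModel("exponential", 0.0, 1e-12, 200.0)
        cv = loo_cv(coords, vals, vg)
        assert cv.rmse < 1e-6

    def test_total_exclusion_marks_points_unpredictable(self, rng):
        coords = rng.uniform(0, 100, (10, 2))
        vals = rng.normal(size=10)
        vg = VariogramModel("exponential", 0.0, 1.0, 50.0)
        cv = loo_cv(coords, vals, vg, exclusion_radius=1e6)
        assert cv.n_unpredictable == 10
        assert np.isnan(cv.rmse)

    def test_rmse_grows_with_exclusion_radius_on_average(self):
        # correlation decays with distance, so excluding close predictors
        # degrades the CV error in expectation over scenes
        rmse0, rmse200 = [], []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            coords = rng.uniform(0, 1000, (150, 2))
            z = simulate_gaussian_field(coords, 0.5, 300.0, rng)
            vg = fit_variogram(coords, z)
            rmse0.append(loo_cv(coords, z, vg, 0.0).rmse)
            rmse200.append(loo_cv(coords, z, vg, 200.0).rmse)
        assert np.mean(rmse200) > np.mean(rmse0)
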