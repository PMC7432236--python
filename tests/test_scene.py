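"""Synthetic district generator: geometry, census, field and oracle checks."""

import io

import numpy as np
import pandas as pd
import pytest

from rfmap.exceptions import InvalidConfigError, UnderdeterminedDesignError
from rfmap.io import write_scene
from rfmap.kriging import empirical_variogram, rss_combine_bands
from rfmap.scene import (
    D_MIN,
    G_AMP,
    DOWNLINK_PROFILE_BANDS,
    SceneConfig,
    diurnal_shape,
    gen_district,
    gen_drive_test,
    gen_indoor_training,
    gen_sensor_series,
    indoor_domain,
    sar_oracle,
)


class TestDistrict:
    def test_grid_tiles_extent_exactly(self, small_scene):
        g = small_scene.grid
        assert g.n_cells == 100
        assert g.nx == g.ny == 10
        centers = g.centers()
        assert centers.shape == (100, 2)
        assert centers[0] == pytest.approx([50.0, 50.0])

    def test_every_building_lies_in_a_zone(self, small_scene):
        union = None
        for geom in small_scene.zones["geometry"]:
            union = geom if union is None else union.union(geom)
        for b in small_scene.buildings["geometry"]:
            assert b.intersection(union).area > 0

    def test_zone_populations_sum_to_district_exactly(self, small_scene):
        cfg = small_scene.config
        z = small_scene.zones
        assert z["pop_child"].sum() + z["pop_adult"].sum() == cfg.population
        assert z["workers"].sum() == cfg.workers

    def test_buildings_have_positive_floor_area_and_known_use(self, small_scene):
        b = small_scene.buildings
        assert (b["floors"] >= 1).all()
        assert all(g.area > 0 for g in b["geometry"])
        assert set(b["declared_use"]) <= {"dwelling", "office", "mixed"}

    def test_same_seed_reproduces_scene_byte_identically(self, tmp_path):
        cfg = SceneConfig(seed=42)
        for sub in ("a", "b"):
            scene = gen_district(cfg)
            drive = gen_drive_test(cfg, 50)
            sens = gen_sensor_series(cfg, 2, 1)
            write_scene(scene, tmp_path / sub, measurements=drive, sensors=sens)
        for name in ("scene.yml", "zones.geojson", "buildings.geojson",
                     "measurements.csv", "sensors.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_zero_buildings_is_a_valid_degenerate_scene(self):
        scene = gen_district(SceneConfig(n_buildings=0, seed=1))
        assert len(scene.buildings) == 0

    def test_zero_area_extent_rejected(self):
        with pytest.raises(InvalidConfigError):
            SceneConfig(extent=(0, 0, 0, 100))

    def test_drive_test_density_matches_campaign_geometry(self):
        # 1100 points over a 14 x 33 cell grid: about 2.4 points per cell
        cfg = SceneConfig(extent=(0, 0, 1400, 3300), seed=0)
        scene = gen_district(cfg)
        assert scene.grid.n_cells == 462
        assert 1100 / scene.grid.n_cells == pytest.approx(2.4, abs=0.1)


class TestDriveTest:
    def test_points_inside_extent_with_positive_field(self):
        cfg = SceneConfig(seed=2)
        df = gen_drive_test(cfg, 200)
        x0, y0, x1, y1 = cfg.extent
        assert ((df.x >= x0) & (df.x <= x1)).all()
        assert ((df.y >= y0) & (df.y <= y1)).all()
        assert (df.E_vpm > 0).all()

    def test_zero_log_variance_gives_median_level_everywhere(self):
        cfg = SceneConfig(log_variance=0.0, hotspots=(), seed=3)
        df = gen_drive_test(cfg, 50)
        total = rss_combine_bands(df)
        assert total["E_vpm"].to_numpy() == pytest.approx(
            np.full(50, cfg.median_level)
        )

    def test_vanishing_range_leaves_no_spatial_structure(self):
        # sill of the short-lag bins matches the long-lag bins when the
        # correlation range is tiny: the variogram is flat (pure nugget)
        cfg = SceneConfig(
            correlation_range_m=1e-3, hotspots=(), log_variance=0.5, seed=4
        )
        df = gen_drive_test(cfg, 2000)
        total = rss_combine_bands(df)
        coords = total[["x", "y"]].to_numpy()
        emp = empirical_variogram(coords, np.log(total["E_vpm"].to_numpy()))
        gam = emp["semivariance"].to_numpy()
        assert gam[:3].mean() == pytest.approx(gam[-3:].mean(), rel=0.15)

    def test_truth_at_returns_joint_realization(self):
        cfg = SceneConfig(seed=5)
        pts = np.array([[10.0, 10.0], [500.0, 500.0]])
        df, truth = gen_drive_test(cfg, 30, truth_at=pts)
        assert truth.shape == (2,)
        assert np.isfinite(truth).all()


class TestSensorSeries:
    def test_constant_series_without_diurnal_or_noise(self):
        cfg = SceneConfig(
            diurnal_amplitude={b: 0.0 for b in DOWNLINK_PROFILE_BANDS},
            sensor_noise_sigma=0.0,
            seed=6,
        )
        df = gen_sensor_series(cfg, 2, 2)
        for _, g in df.groupby(["node_id", "band"]):
            assert g["E_vpm"].nunique() == 1

    def test_node_levels_differ_between_nodes(self):
        df = gen_sensor_series(SceneConfig(seed=7), 3, 1)
        means = df.groupby("node_id")["E_vpm"].mean()
        assert means.nunique() == 3

    def test_timestamps_strictly_increasing_per_node(self):
        df = gen_sensor_series(SceneConfig(seed=8), 2, 1, sample_period_s=3600)
        for _, g in df.groupby(["node_id", "band"]):
            assert g["timestamp"].is_monotonic_increasing

    @pytest.mark.parametrize("n_nodes", [36, 10])
    def test_network_size_presets(self, n_nodes):
        df = gen_sensor_series(SceneConfig(seed=9), n_nodes, 1)
        assert df["node_id"].nunique() == n_nodes

    def test_diurnal_shape_is_normalized_power_profile(self, default_config):
        s = diurnal_shape(default_config, DOWNLINK_PROFILE_BANDS[0])
        assert s.shape == (24,)
        assert s.mean() == pytest.approx(1.0)
        assert (s > 0).all()


class TestIndoorOracle:
    def test_oracle_matches_direct_formula_on_hand_points(self):
        # five hand-picked designs evaluated against the stated closed form
        pts = np.array(
            [
                [1.5, 2.6, 1.5, 2.0, 0.0],
                [0.0, 2.4, 3.0, 4.0, np.pi],
                [1.0, 2.8, 1.0, 0.0, np.pi / 2],
                [2.0, 2.5, 2.0, 1.0, 1.0],
                [0.5, 2.4, 0.5, 0.1, 3.0],
            ]
        )
        expected = []
        for s, hs, x, y, th in pts:
            d2 = (x - s) ** 2 + y**2 + (1.0 - hs) ** 2
            expected.append(
                1.5 * (1 + G_AMP * np.cos(th)) / max(d2, D_MIN**2)
            )
        assert sar_oracle(pts) == pytest.approx(expected, rel=1e-12)

    def test_colocated_child_hits_clamped_maximum(self):
        # the clamp bounds the dose by p0 * (1 + G_AMP) / d_min^2
        dom = indoor_domain()
        rng = np.random.default_rng(0)
        X = rng.uniform(dom[:, 0], dom[:, 1], (2000, 5))
        peak = 1.5 * (1 + G_AMP) / D_MIN**2
        assert (sar_oracle(X) <= peak + 1e-12).all()

    def test_doubling_power_doubles_all_responses(self):
        cfg = SceneConfig(seed=10)
        X, Y1 = gen_indoor_training(cfg, 50)
        Y2 = sar_oracle(X, p0=3.0)
        assert Y2 == pytest.approx(2.0 * Y1)

    def test_design_is_space_filling_within_domain(self):
        cfg = SceneConfig(seed=11)
        X, Y = gen_indoor_training(cfg, 200)
        dom = indoor_domain()
        assert (X >= dom[:, 0]).all() and (X <= dom[:, 1]).all()
        # LHS stratification: each fifth of each axis holds 1/5 of points
        for j in range(5):
            u = (X[:, j] - dom[j, 0]) / (dom[j, 1] - dom[j, 0])
            counts = np.histogram(u, bins=5, range=(0, 1))[0]
            assert counts.min() >= 20

    def test_underdetermined_design_rejected(self):
        with pytest.raises(UnderdeterminedDesignError):
            gen_indoor_training(SceneConfig(seed=0), 10, min_coefficients=26)

    def test_invalid_room_rejected(self):
        with pytest.raises(InvalidConfigError):
            gen_indoor_training(SceneConfig(seed=0), 10, room=(0.0, 4.0))
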