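import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from cellpeer.shape_features import Contour, shape_scalars
from cellpeer.synth import (
    ShapeParams,
    SimulationConfig,
    canonical_benchmark_config,
    simulate_brownian_track,
    simulate_experiment,
    simulate_ou_track,
    simulate_shape_series,
    write_experiment,
)


def small_config(**kw):
    base = dict(n_classes=2, videos_per_class=1, clusters_per_video=2,
                cells_per_cluster=3, n_frames=80, with_contours=False, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_identical_config_and_seed(self):
        a = simulate_experiment(small_config())
        b = simulate_experiment(small_config())
        assert len(a.trajectories) == len(b.trajectories)
        for ta, tb in zip(a.trajectories, b.trajectories):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.y, tb.y)
        assert a.ground_truth.equals(b.ground_truth)

    def test_different_seeds_differ(self):
        a = simulate_experiment(small_config(seed=5))
        b = simulate_experiment(small_config(seed=6))
        assert not np.array_equal(a.trajectories[0].x, b.trajectories[0].x)

    def test_brownian_seed_reproducible(self):
        t1 = simulate_brownian_track(1.0, 50, seed=9)
        t2 = simulate_brownian_track(1.0, 50, seed=9)
        np.testing.assert_array_equal(t1.x, t2.x)


class TestContamination:
    def test_zero_contamination_no_outliers(self):
        exp = simulate_experiment(small_config(contamination_fraction=0.0))
        assert not exp.ground_truth["is_outlier"].any()

    def test_contamination_frequency(self):
        cfg = small_config(cells_per_cluster=50, clusters_per_video=2,
                           contamination_fraction=0.3, n_frames=60)
        exp = simulate_experiment(cfg)
        frac = exp.ground_truth["is_outlier"].mean()
        assert abs(frac - 0.3) < 0.08  # binomial tolerance, n = 200

    def test_contaminated_speed_distribution_separates(self):
        """Outliers at speed x3 must be distinguishable from canonical
        tracks by per-track mean speed (AUC > 0.8)."""
        cfg = small_config(cells_per_cluster=25, n_frames=120,
                           contamination_fraction=0.3)
        exp = simulate_experiment(cfg)
        gt = exp.ground_truth.set_index(["video_id", "track_id"])["is_outlier"]
        speeds = {True: [], False: []}
        for tr in exp.trajectories:
            v = np.mean(np.hypot(np.diff(tr.x), np.diff(tr.y)))
            speeds[bool(gt.loc[(tr.video_id, tr.track_id)])].append(v)
        u, _ = mannwhitneyu(speeds[True], speeds[False])
        auc = u / (len(speeds[True]) * len(speeds[False]))
        assert auc > 0.8


class TestMotilityCalibration:
    def test_mean_speed_converges(self):
        # 100 tracks x 300 frames within 10% of the configured mean speed
        for target in (0.4, 1.2):
            speeds = [
                np.mean(np.hypot(np.diff(tr.x), np.diff(tr.y)))
                for i in range(100)
                for tr in [simulate_ou_track(target, 8.0, 300,
                                             rng=np.random.default_rng(i))]
            ]
            assert np.mean(speeds) == pytest.approx(target, rel=0.10)

    def test_class_speed_separation_auc(self):
        """Two classes at 0.2 vs 1.0 px/min: per-track mean speed AUC > 0.9."""
        a = [np.mean(np.hypot(np.diff(t.x), np.diff(t.y)))
             for i in range(50)
             for t in [simulate_ou_track(0.2, 5.0, 100, rng=np.random.default_rng(i))]]
        b = [np.mean(np.hypot(np.diff(t.x), np.diff(t.y)))
             for i in range(50)
             for t in [simulate_ou_track(1.0, 5.0, 100,
                                         rng=np.random.default_rng(500 + i))]]
        u, _ = mannwhitneyu(b, a)
        assert u / 2500 > 0.9

    def test_brownian_d_zero_is_immobile(self):
        tr = simulate_brownian_track(0.0, 30, seed=1)
        assert np.all(tr.x == tr.x[0]) and np.all(tr.y == tr.y[0])

    def test_brownian_msd_slope(self):
        from cellpeer.motility_features import msd_loglog_slope

        slopes = [msd_loglog_slope(simulate_brownian_track(1.0, 2000, seed=s))
                  for s in range(10)]
        assert 0.85 < np.mean(slopes) < 1.15


class TestShapeSeries:
    def test_pure_ellipse_solid_and_convex(self):
        params = ShapeParams(400.0, 0.5, pseudopod_rate=0.0, area_noise=0.0, ecc_noise=0.0)
        polys = simulate_shape_series(params, 5, seed=2)
        for p in polys:
            s = shape_scalars(Contour(p))
            assert s.solidity == pytest.approx(1.0, abs=1e-6)

    def test_zero_eccentricity_target(self):
        params = ShapeParams(400.0, 0.0, 0.0, area_noise=0.0, ecc_noise=0.0)
        s = shape_scalars(Contour(simulate_shape_series(params, 1, seed=0)[0]))
        assert s.eccentricity < 0.05

    def test_pseudopods_lower_solidity(self):
        base = ShapeParams(400.0, 0.3, pseudopod_rate=0.0)
        bumpy = ShapeParams(400.0, 0.3, pseudopod_rate=1.0)
        sol = {}
        for name, params in (("base", base), ("bumpy", bumpy)):
            polys = simulate_shape_series(params, 100, seed=7)
            sol[name] = np.mean([shape_scalars(Contour(p)).solidity for p in polys])
        assert sol["bumpy"] < sol["base"]

    def test_pseudopod_frame_strictly_nonconvex(self):
        params = ShapeParams(400.0, 0.3, pseudopod_rate=1.0, area_noise=0.0, ecc_noise=0.0)
        polys = simulate_shape_series(params, 10, seed=3)
        for p in polys:
            assert shape_scalars(Contour(p)).solidity < 1.0

    def test_degenerate_parameters_raise(self):
        with pytest.raises(ValueError):
            ShapeParams(0.0, 0.5, 0.0).validate()


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(n_frames=0),
        dict(contamination_fraction=1.0),
        dict(dt=0.0),
        dict(mean_speed=(0.4,)),  # wrong length
        dict(mean_speed=(-1.0, 0.5)),
        dict(persistence_time=(0.0, 5.0)),
    ])
    def test_invalid_configs_raise(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)

    def test_excess_diffusivity_rejected(self):
        with pytest.raises(ValueError, match="diffusivity"):
            simulate_ou_track(0.1, 5.0, 10, diffusivity=1.0)

    def test_negative_brownian_d(self):
        with pytest.raises(ValueError):
            simulate_brownian_track(-1.0, 10)


class TestStructure:
    def test_layout_counts(self):
        cfg = small_config()
        exp = simulate_experiment(cfg)
        assert len(exp.experiment.videos) == 2
        assert len(exp.trajectories) == 2 * 2 * 3
        gt = exp.ground_truth
        assert set(gt["cluster_id"]) == {1, 2}
        assert (gt.groupby("video_id").size() == 6).all()

    def test_benchmark_config(self):
        cfg = canonical_benchmark_config(seed=3)
        assert cfg.n_classes == 3 and cfg.videos_per_class == 4
        assert cfg.contamination_fraction == 0.2
        assert cfg.seed == 3

    def test_contours_follow_tracks(self):
        cfg = small_config(with_contours=True, n_frames=20)
        exp = simulate_experiment(cfg)
        tr = exp.trajectories[0]
        polys = exp.experiment.contours[(tr.video_id, tr.track_id)]
        assert len(polys) == 20
        center = polys[5].mean(axis=0)
        assert np.hypot(center[0] - tr.x[5], center[1] - tr.y[5]) < 5.0


def test_write_experiment_roundtrip(tmp_path):
    exp = simulate_experiment(small_config(with_contours=True, n_frames=20))
    write_experiment(exp, tmp_path)
    for name in ("tracks.csv", "contours.csv", "ground_truth.csv",
                 "config.json", "videos.csv"):
        assert (tmp_path / name).exists()
    from cellpeer.tracks import read_contours_csv, read_tracks_csv

    back = read_tracks_csv(tmp_path / "tracks.csv")
    assert len(back) == len(exp.trajectories)
    contours = read_contours_csv(tmp_path / "contours.csv")
    key = (exp.trajectories[0].video_id, exp.trajectories[0].track_id)
    np.testing.assert_allclose(contours[key][0],
                               exp.experiment.contours[key][0], atol=1e-6)
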