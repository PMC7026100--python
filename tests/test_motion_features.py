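import numpy as np
import pytest

from dyadkit.config import RunConfig
from dyadkit.motion_features import (MOTION_FEATURES, curvature,
                                     detect_pauses, kinematics,
                                     max_pair_distance, motion_features,
                                     movement_units, select_window,
                                     spatial_descriptors, visible_runs)


def brute_force_diameter(points):
    best = 0.0
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            best = max(best, float(np.hypot(*(points[i] - points[j]))))
    return best


class TestSelectWindow:

    def test_fully_visible_takes_first_minute(self, make_traj):
        n = 180 * 25
        traj = make_traj(np.zeros(n), np.zeros(n))
        win = select_window(traj, 60)
        assert len(win) == 1500
        assert win.frames[0] == 0

    def test_selects_the_visible_minute(self, make_traj):
        n = 180 * 25
        visible = np.zeros(n, dtype=bool)
        visible[60 * 25:120 * 25] = True
        traj = make_traj(np.zeros(n), np.zeros(n), visible=visible)
        win = select_window(traj, 60)
        assert win.visible.all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_maximum(self, make_traj, seed):
        rng = np.random.default_rng(seed)
        n = 400
        visible = rng.random(n) < 0.6
        traj = make_traj(np.zeros(n), np.zeros(n), visible=visible, fps=25)
        n_win = 100
        win = select_window(traj, n_win / 25)
        best = max(visible[s:s + n_win].mean() for s in range(n - n_win + 1))
        assert win.visible.mean() == pytest.approx(best)

    def test_short_trajectory_returned_whole(self, make_traj):
        traj = make_traj(np.zeros(100), np.zeros(100))
        assert len(select_window(traj, 60)) == 100


class TestSpatial:

    def test_unit_square_corners(self, make_traj):
        traj = make_traj([0, 1, 1, 0], [0, 0, 1, 1])
        d = spatial_descriptors(traj)
        assert d["xRange"] == 1.0 and d["yRange"] == 1.0
        assert d["maxPairDist"] == pytest.approx(np.sqrt(2))

    def test_repeated_point_all_zero(self, make_traj):
        traj = make_traj(np.full(10, 0.3), np.full(10, 0.7))
        d = spatial_descriptors(traj)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in d.values())

    def test_single_visible_frame_undefined(self, make_traj):
        traj = make_traj([0.1, 0.2], [0.1, 0.2], visible=[True, False])
        d = spatial_descriptors(traj)
        assert all(np.isnan(v) for v in d.values())

    @pytest.mark.parametrize("n", [50, 300])
    def test_farthest_pair_matches_brute_force(self, n, rng):
        pts = rng.random((n, 2))
        assert max_pair_distance(pts) == pytest.approx(brute_force_diameter(pts))

    def test_invariant_max_pair_at_least_axis_ranges(self, make_traj, rng):
        pts = rng.random((40, 2))
        traj = make_traj(pts[:, 0], pts[:, 1])
        d = spatial_descriptors(traj)
        assert d["maxPairDist"] >= max(d["xRange"], d["yRange"]) - 1e-12


class TestKinematics:

    def test_uniform_linear_motion(self, make_traj):
        d, fps = 0.01, 25.0
        x = d * np.arange(200)
        traj = make_traj(x, np.zeros(200), fps=fps)
        speed, accel, stats = kinematics(traj, smooth_window=1)
        ok = ~np.isnan(speed)
        np.testing.assert_allclose(speed[ok], d * fps, rtol=1e-9)
        assert stats["accMax"] == pytest.approx(0.0, abs=1e-9)
        assert stats["pathLength"] == pytest.approx(d * 199)

    def test_stationary_all_speeds_zero(self, make_traj):
        traj = make_traj(np.full(100, 0.5), np.full(100, 0.5))
        speed, _, stats = kinematics(traj)
        assert stats["velMax"] == 0.0

    def test_sinusoid_velmax_analytic(self, make_traj):
        t = np.arange(0, 10, 1 / 25)
        traj = make_traj(np.sin(2 * np.pi * t), np.zeros(len(t)))
        _, _, stats = kinematics(traj, smooth_window=1)
        assert stats["velMax"] == pytest.approx(2 * np.pi, rel=0.02)

    def test_never_differentiates_across_gaps(self, make_traj):
        x = np.concatenate([np.zeros(100), np.full(100, 10.0)])
        visible = np.ones(200, dtype=bool)
        visible[100] = False  # a jump hidden by a gap
        traj = make_traj(x, np.zeros(200), visible=visible)
        speed, _, stats = kinematics(traj, smooth_window=1)
        assert stats["velMax"] == 0.0

    def test_too_short_runs_undefined(self, make_traj):
        traj = make_traj([0, 1, 2, 3], [0] * 4,
                         visible=[True, True, False, True])
        _, _, stats = kinematics(traj)
        assert np.isnan(stats["velMean"])


class TestPauses:

    def test_whole_minute_still(self):
        speed = np.zeros(1500)
        pauses, stats = detect_pauses(speed, threshold=0.1, fps=25)
        assert len(pauses) == 1
        assert stats["pauseRelTime"] == pytest.approx(1.0)

    def test_three_second_run_too_short(self):
        speed = np.ones(1500)
        speed[100:175] = 0.0  # 3 s below threshold
        pauses, stats = detect_pauses(speed, 0.5, 25, min_dur_s=4)
        assert pauses == []
        assert stats["pauseCount"] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_run_scan(self, seed):
        rng = np.random.default_rng(seed)
        speed = rng.random(2000)
        speed[rng.random(2000) < 0.05] = np.nan
        thr, fps, min_dur = 0.6, 25.0, 1.0
        pauses, _ = detect_pauses(speed, thr, fps, min_dur)
        # oracle: explicit run-length scan
        expected = []
        run = 0
        for i, s in enumerate(list(speed) + [np.nan]):
            if not np.isnan(s) and s < thr:
                run += 1
            else:
                if run >= int(min_dur * fps):
                    expected.append((i - run, i))
                run = 0
        assert [(round(p.start_s * fps), round(p.end_s * fps))
                for p in pauses] == expected

    def test_pause_never_spans_gap(self):
        speed = np.zeros(300)
        speed[150] = np.nan
        pauses, _ = detect_pauses(speed, 0.1, 25, min_dur_s=4)
        assert len(pauses) == 2

    def test_movement_units_counts_bursts(self):
        speed = np.array([0, 1, 1, 0, 0, 2, 0, 3, 3, 3], dtype=float)
        assert movement_units(speed, 0.5) == 3


class TestCurvature:

    def test_circle_curvature_is_inverse_radius(self, make_traj):
        R = 2.0
        t = np.arange(0, 12, 1 / 25)
        traj = make_traj(R * np.cos(t), R * np.sin(t))
        kappa, stats = curvature(traj, smooth_window=1)
        ok = ~np.isnan(kappa)
        assert ok.sum() > 200
        np.testing.assert_allclose(kappa[ok], 1 / R, rtol=0.02)
        assert stats["curvMean"] == pytest.approx(1 / R, rel=0.02)

    def test_straight_line_zero_curvature(self, make_traj):
        t = np.arange(300) / 25
        traj = make_traj(t, 2 * t)
        kappa, stats = curvature(traj, smooth_window=1)
        assert stats["curvMax"] == pytest.approx(0.0, abs=1e-6)

    def test_parabola_vertex_curvature(self, make_traj):
        # y = x^2 traversed at unit x-speed: kappa(0) = 2
        x = np.arange(-1, 1, 1 / 25)
        traj = make_traj(x, x ** 2, fps=25)
        kappa, _ = curvature(traj, smooth_window=1, speed_epsilon=1e-6)
        i0 = int(np.argmin(np.abs(x)))
        assert kappa[i0] == pytest.approx(2.0, rel=0.02)

    def test_needs_five_frame_runs(self, make_traj):
        traj = make_traj([0, 1, 2, 3], [0, 1, 0, 1])
        kappa, stats = curvature(traj)
        assert np.isnan(stats["curvMean"])


class TestMotionFeatureVector:

    def test_stationary_fully_visible(self, make_traj):
        traj = make_traj(np.full(1500, 0.5), np.full(1500, 0.5))
        feats = motion_features(traj)
        assert feats["pauseCount"] == 1
        assert feats["velMax"] == 0.0
        assert feats["visibleFraction"] == 1.0

    def test_planted_pauses_counted(self, make_traj):
        rng = np.random.default_rng(0)
        segments = []
        for k in range(3):
            segments.append(np.cumsum(rng.normal(0.01, 0.003, 250)))  # moving
            segments.append(np.full(125, 0.0))                        # 5 s still
        x = np.concatenate(segments) + 5.0
        traj = make_traj(x, np.zeros(len(x)), fps=25)
        feats = motion_features(traj)
        assert feats["pauseCount"] == 3

    def test_vector_schema(self, make_traj, rng):
        traj = make_traj(rng.random(1500), rng.random(1500))
        feats = motion_features(traj)
        assert list(feats) == MOTION_FEATURES
        assert len(feats) == 21

    def test_scale_equivariance(self, rng, make_traj):
        pts = np.cumsum(rng.normal(0, 0.01, (400, 2)), axis=0)
        traj = make_traj(pts[:, 0], pts[:, 1])
        scaled = make_traj(3.0 * pts[:, 0], 3.0 * pts[:, 1])
        f1 = motion_features(traj)
        f2 = motion_features(scaled)
        for name in ("xRange", "yRange", "xSd", "ySd", "maxPairDist",
                     "pathLength", "velMax"):
            assert f2[name] == pytest.approx(3.0 * f1[name], rel=1e-9)
        for name in ("pauseRelTime", "visibleFraction", "pauseCount",
                     "movementUnitCount"):
            assert f2[name] == pytest.approx(f1[name])

    def test_time_reversal_invariance(self, rng, make_traj):
        pts = np.cumsum(rng.normal(0, 0.01, (400, 2)), axis=0)
        visible = rng.random(400) < 0.9
        traj = make_traj(pts[:, 0], pts[:, 1], visible=visible)
        rev = make_traj(pts[::-1, 0], pts[::-1, 1], visible=visible[::-1])
        f1, f2 = motion_features(traj), motion_features(rev)
        for name in ("xRange", "yRange", "xSd", "ySd", "maxPairDist",
                     "pauseTotalDur_s", "pauseCount"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-9, abs=1e-12)

    def test_fully_occluded_gives_missing_markers(self, make_traj):
        traj = make_traj(np.zeros(100), np.zeros(100),
                         visible=np.zeros(100, dtype=bool))
        feats = motion_features(traj)
        assert np.isnan(feats["velMean"])
        assert np.isnan(feats["xRange"])
        assert len(feats) == 21


def test_visible_runs_split_on_dropped_frames(make_traj):
    traj = make_traj([0, 1, 2, 3], [0] * 4, frames=np.array([0, 1, 5, 6]))
    runs = visible_runs(traj)
    assert [(r.start, r.stop) for r in runs] == [(0, 2), (2, 4)]
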