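"""Trajectory-to-measure conversion: geometry, efficiency, session summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fovadapt.metrics import (
    DegenerateSessionError,
    EmptyTrialError,
    EndReason,
    Stage,
    TrialMetrics,
    TrialRecord,
    adjusted_distance,
    angular_error,
    baseline_criterion,
    clean_trajectory,
    compute_trial_metrics,
    is_success,
    path_length,
    session_efficiency,
    summarize_session,
)


def _tm(success, ang, ln, se, et, fish="f0", ses=0, trial=0):
    return TrialMetrics(
        fish_id=fish,
        stage=Stage.BASELINE,
        session_index=ses,
        trial_index=trial,
        success=success,
        angular_error=ang,
        path_length=ln,
        se=se,
        et=et,
    )


class TestCleanTrajectory:
    def test_single_missing_frame_interpolated_at_midpoint(self):
        t = np.array([0.0, 0.5, 1.0])
        x = np.array([0.0, np.nan, 0.0])
        y = np.array([0.0, np.nan, 0.2])
        tc, xc, yc = clean_trajectory(t, x, y, smooth_window=1)
        assert len(tc) == 3
        assert xc[1] == pytest.approx(0.0)
        assert yc[1] == pytest.approx(0.1)

    def test_no_gaps_is_identity_without_smoothing(self):
        t = np.linspace(0, 5, 11)
        x = np.linspace(0, 1, 11)
        y = np.linspace(0, 2, 11)
        tc, xc, yc = clean_trajectory(t, x, y, smooth_window=1)
        np.testing.assert_allclose(xc, x)
        np.testing.assert_allclose(yc, y)

    def test_smoothing_preserves_constant_runs(self):
        t = np.arange(10.0)
        x = np.full(10, 1.5)
        y = np.full(10, -2.0)
        _, xc, yc = clean_trajectory(t, x, y, smooth_window=3)
        np.testing.assert_allclose(xc, x)
        np.testing.assert_allclose(yc, y)

    def test_random_walk_with_dropped_frames_matches_interp_oracle(self, rng):
        n = 200
        t = np.arange(n, dtype=float) * 0.1
        x = np.cumsum(rng.normal(0, 0.05, n))
        y = np.cumsum(rng.normal(0, 0.05, n))
        drop = rng.random(n) < 0.10
        drop[[0, -1]] = False
        xd, yd = x.copy(), y.copy()
        xd[drop] = np.nan
        yd[drop] = np.nan
        tc, xc, yc = clean_trajectory(t, xd, yd, smooth_window=1)
        assert len(tc) == n  # all gaps are < 1 s, so every frame is refilled
        # independent point-wise linear interpolation oracle
        xo = np.interp(t, t[~drop], x[~drop])
        yo = np.interp(t, t[~drop], y[~drop])
        np.testing.assert_allclose(xc, xo, atol=1e-12)
        np.testing.assert_allclose(yc, yo, atol=1e-12)

    def test_long_gaps_stay_removed(self):
        t = np.array([0.0, 0.2, 3.0, 3.2])
        x = np.array([0.0, np.nan, np.nan, 1.0])
        y = np.zeros(4)
        tc, _, _ = clean_trajectory(t, x, y, smooth_window=1, max_gap_s=1.0)
        assert list(tc) == [0.0, 3.2]

    def test_fewer_than_two_valid_samples_rejected(self):
        with pytest.raises(EmptyTrialError, match="empty trial"):
            clean_trajectory(
                np.array([0.0, 1.0]), np.array([0.0, np.nan]), np.array([0.0, np.nan])
            )


class TestPathLength:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0, 0, 1], [0, 1, 1], 2.0),
            (np.zeros(10), np.linspace(0, 2.5, 10), 2.5),
        ],
    )
    def test_known_polylines(self, x, y, expected):
        assert path_length(x, y) == pytest.approx(expected)

    def test_matches_pairwise_bruteforce(self, rng):
        pts = rng.normal(size=(100, 2))
        brute = sum(
            float(np.hypot(pts[i + 1, 0] - pts[i, 0], pts[i + 1, 1] - pts[i, 1]))
            for i in range(99)
        )
        assert path_length(pts[:, 0], pts[:, 1]) == pytest.approx(brute, abs=1e-12)

    def test_single_sample_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert path_length([1.0], [2.0]) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(-np.pi, np.pi),
        st.floats(-5, 5),
        st.floats(-5, 5),
        st.integers(0, 1000),
    )
    def test_rigid_motion_invariance(self, theta, dx, dy, seed):
        pts = np.random.default_rng(seed).normal(size=(20, 2))
        c, s = np.cos(theta), np.sin(theta)
        rot = pts @ np.array([[c, -s], [s, c]]).T + [dx, dy]
        assert path_length(rot[:, 0], rot[:, 1]) == pytest.approx(
            path_length(pts[:, 0], pts[:, 1]), rel=1e-9
        )


class TestAngularError:
    def test_perfect_aim_is_zero(self):
        assert angular_error((0, 0), (0, 2.5), (0, 2.5)) == pytest.approx(0.0)

    def test_clockwise_rotation_of_target_direction_is_positive(self):
        # end = target direction rotated 45 degrees clockwise
        end = (np.sin(np.radians(45)), np.cos(np.radians(45)))
        assert angular_error((0, 0), end, (0, 1)) == pytest.approx(45.0)

    def test_random_triples_match_cross_dot_oracle(self, rng):
        for _ in range(500):
            start, end, target = rng.normal(size=(3, 2))
            if np.allclose(end, start) or np.allclose(target, start):
                continue
            u = target - start
            v = end - start
            cross = u[0] * v[1] - u[1] * v[0]
            dot = u @ v
            oracle = -np.degrees(np.arctan2(cross, dot))
            if oracle <= -180.0:
                oracle += 360.0
            assert angular_error(start, end, target) == pytest.approx(oracle, abs=1e-9)

    def test_zero_displacement_flags_trial(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(angular_error((1, 1), (1, 1), (0, 2)))

    def test_target_equal_start_rejected(self):
        with pytest.raises(ValueError):
            angular_error((0, 0), (1, 1), (0, 0))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_antisymmetric_under_reflection(self, seed):
        r = np.random.default_rng(seed)
        start, end, target = r.normal(size=(3, 2))
        if np.allclose(end, start) or np.allclose(target, start):
            return
        # reflect end about the start->target axis
        u = (target - start) / np.linalg.norm(target - start)
        v = end - start
        refl = start + 2 * (v @ u) * u - v
        a1 = angular_error(start, end, target)
        a2 = angular_error(start, refl, target)
        if abs(abs(a1) - 180.0) < 1e-6:
            return  # both representations of the back direction are valid
        assert a2 == pytest.approx(-a1, abs=1e-9)


class TestSuccess:
    def test_center_hit(self):
        assert is_success((0, 2.5), (0, 2.5))

    def test_far_miss(self):
        assert not is_success((10, 0), (0, 2.5))

    def test_boundary_point_counts_as_success(self):
        assert is_success((0.25, 2.5), (0, 2.5), target_radius=0.25)

    def test_recorded_flag_takes_precedence(self):
        assert is_success((10, 0), (0, 2.5), recorded=True)
        assert not is_success((0, 2.5), (0, 2.5), recorded=False)


class TestEfficiencyAndAdjustedDistance:
    def test_straight_lines_give_unit_efficiency(self):
        assert session_efficiency([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_simple_ratio(self):
        assert session_efficiency([4.0, 6.0], [2.0, 3.0]) == pytest.approx(2.0)

    def test_random_polylines_match_recomputation(self, rng):
        lens = rng.uniform(1, 10, 6)
        ses = rng.uniform(0.5, 5, 6)
        assert session_efficiency(lens, ses) == pytest.approx(lens.sum() / ses.sum())

    def test_degenerate_session_raises_unless_allowed(self):
        with pytest.raises(DegenerateSessionError):
            session_efficiency([1.0], [0.0])
        with pytest.warns(UserWarning):
            assert session_efficiency([1.0], [0.0], allow_degenerate=True) == 1.0

    def test_success_excludes_eal(self):
        assert adjusted_distance(3.0, 1.0, True, 1.5) == pytest.approx(3.0)

    def test_failure_adds_scaled_end_to_target(self):
        assert adjusted_distance(4.0, 1.0, False, 1.5) == pytest.approx(5.5)

    def test_failed_trials_match_formula_oracle(self, rng):
        for _ in range(50):
            ln, et, eff = rng.uniform(0.1, 10, 3)
            assert adjusted_distance(ln, et, False, eff) == pytest.approx(ln + eff * et)

    def test_adjusted_at_least_path_length(self, rng):
        for _ in range(100):
            ln, et, eff = rng.uniform(0.0, 10, 3)
            succ = rng.random() < 0.5
            assert adjusted_distance(ln, et, succ, eff) >= ln - 1e-12


class TestSummarizeSession:
    def test_success_count(self):
        trials = [_tm(i < 4, 0.0, 3.0, 2.5, 0.1, trial=i) for i in range(6)]
        sm = summarize_session(trials)
        assert sm.success_count == 4

    def test_odd_median(self):
        trials = [_tm(True, a, 3.0, 2.5, 0.0, trial=i) for i, a in enumerate([-10, 0, 10])]
        assert summarize_session(trials).median_angular_error == pytest.approx(0.0)

    def test_even_median_uses_mean_of_middle(self):
        trials = [_tm(True, a, 3.0, 2.5, 0.0, trial=i) for i, a in enumerate([1, 2, 3, 4])]
        assert summarize_session(trials).median_angular_error == pytest.approx(2.5)

    def test_undefined_errors_excluded_but_counted_as_failures(self):
        trials = [
            _tm(False, np.nan, 0.0, 0.0, 2.5, trial=0),
            _tm(True, 5.0, 3.0, 2.5, 0.0, trial=1),
        ]
        sm = summarize_session(trials)
        assert sm.median_angular_error == pytest.approx(5.0)
        assert sm.success_count == 1

    def test_no_defined_errors_warns_and_returns_nan(self):
        trials = [_tm(False, np.nan, 0.0, 0.0, 2.5)]
        with pytest.warns(UserWarning):
            sm = summarize_session(trials, allow_degenerate=True)
        assert np.isnan(sm.median_angular_error)

    def test_order_invariance(self, rng):
        trials = [
            _tm(bool(rng.random() < 0.5), float(rng.normal(0, 20)), float(rng.uniform(2, 8)),
                float(rng.uniform(1, 3)), float(rng.uniform(0, 2)), trial=i)
            for i in range(6)
        ]
        a = summarize_session([trials[i] for i in [0, 1, 2, 3, 4, 5]])
        b = summarize_session([trials[i] for i in [5, 3, 1, 0, 4, 2]])
        assert a.success_count == b.success_count
        assert a.median_angular_error == pytest.approx(b.median_angular_error)
        assert a.median_adjusted_distance == pytest.approx(b.median_adjusted_distance)

    def test_straight_successful_session_is_ideal(self):
        trials = [_tm(True, 0.0, 2.5, 2.5, 0.0, trial=i) for i in range(6)]
        sm = summarize_session(trials)
        assert sm.efficiency == pytest.approx(1.0)
        assert sm.median_angular_error == pytest.approx(0.0)
        assert all(t.eal == 0.0 for t in trials)


def _session(fish, ses, successes, angle, dist):
    trials = [
        _tm(i < successes, angle, dist, 2.5, 0.5, fish=fish, ses=ses, trial=i)
        for i in range(6)
    ]
    return summarize_session(trials)


class TestBaselineCriterion:
    def test_three_good_sessions_pass(self):
        hist = [_session("f", i, 5, 1.0, 3.0) for i in range(3)]
        ok, idx = baseline_criterion(hist)
        assert ok and idx == 2

    def test_window_median_success_threshold(self):
        # median of {3, 3, 6} is 3 < 4: fails even though one session is perfect
        hist = [_session("f", i, s, 0.0, 3.0) for i, s in enumerate([3, 3, 6])]
        assert baseline_criterion(hist) == (False, None)
        # median of {6, 0, 6} is 6 >= 4: the window qualifies despite the dip
        hist = [_session("f", i, s, 0.0, 3.0) for i, s in enumerate([6, 0, 6])]
        ok, idx = baseline_criterion(hist)
        assert ok and idx == 2

    def test_short_history_is_insufficient(self):
        hist = [_session("f", i, 6, 0.0, 3.0) for i in range(2)]
        assert baseline_criterion(hist) == (False, None)

    def test_cap_at_25_sessions(self):
        hist = [_session("f", i, 0, 60.0, 8.0) for i in range(30)]
        hist += [_session("f", 30 + i, 6, 0.0, 3.0) for i in range(3)]
        ok, _ = baseline_criterion(hist)
        assert not ok

    def test_matches_exhaustive_window_scan_oracle(self, rng):
        # an improving fish: success rises, angle and distance fall
        hist = []
        for i in range(20):
            succ = min(6, int(rng.poisson(1 + 0.3 * i)))
            ang = float(rng.normal(30 * np.exp(-i / 5), 3))
            dist = float(max(2.6, 8 * np.exp(-i / 6) + 2.5 + rng.normal(0, 0.2)))
            hist.append(_session("f", i, succ, ang, dist))
        ok, idx = baseline_criterion(hist)
        # oracle: brute-force scan of every 3-session window
        expected = None
        for end in range(2, 20):
            win = hist[end - 2 : end + 1]
            med_succ = np.median([s.success_count for s in win])
            angs = np.concatenate([s.trial_angular_errors for s in win])
            dists = np.concatenate([s.trial_adjusted_distances for s in win])
            if med_succ >= 4 and abs(np.median(angs)) < 15 and np.median(dists) < 4.5:
                expected = end
                break
        assert ok == (expected is not None)
        assert idx == expected


class TestComputeTrialMetrics:
    def test_end_reason_target_reached_implies_success(self):
        samples = np.column_stack([np.arange(3.0), np.zeros(3), [0, 1, 2]])
        rec = TrialRecord(
            fish_id="f0",
            stage=Stage.BASELINE,
            session_index=0,
            trial_index=0,
            samples=samples,
            start_point=(0, 0),
            target_point=(0, 2.5),
            end_reason=EndReason.TARGET_REACHED,
        )
        tm = compute_trial_metrics(rec)
        assert tm.success
        assert tm.path_length == pytest.approx(2.0)
        assert tm.se == pytest.approx(2.0)
        assert tm.et == pytest.approx(0.5)

    def test_duration_cap_enforced(self):
        samples = np.column_stack([[0.0, 200.0], np.zeros(2), np.zeros(2)])
        with pytest.raises(ValueError, match="duration"):
            TrialRecord("f", Stage.BASELINE, 0, 0, samples, (0, 0), (0, 2.5))
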