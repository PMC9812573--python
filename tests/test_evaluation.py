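"""Evaluation: Pearson CC, motion-class scoring, ANOVA, TAC state machine."""

import numpy as np
import pytest
from scipy import stats

import myodecode as md
from myodecode.evaluation import (
    TACEvaluationError,
    UndefinedCCError,
    completion_rate_at,
)


class TestPearsonCC:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert md.pearson_cc(x, x) == pytest.approx(1.0)

    def test_negated_series(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert md.pearson_cc(x, -x) == pytest.approx(-1.0)

    def test_hand_worked_example(self):
        # (1,2,3) vs (1,3,2): one concordant step, one neutral -> 0.5
        assert md.pearson_cc([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCCError):
            md.pearson_cc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_agrees_with_covariance_formulation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.standard_normal(40)
            y = rng.standard_normal(40) + 0.3 * x
            want = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
            assert md.pearson_cc(x, y) == pytest.approx(want, abs=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        y = 0.7 * x + rng.standard_normal(100)
        assert md.pearson_cc(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)


@pytest.fixture(scope="module")
def scripted():
    script = md.MotionScript.from_pairs(
        [("M0", 1.0), ("M1", 2.0), ("M0", 1.0), ("M6", 2.0),
         ("M0", 1.0), ("M10", 2.0), ("M0", 1.0)]
    )
    measured = md.render_angle_trajectory(script, rate=120.0)
    return script, measured


class TestSegmentAndScore:
    def test_perfect_prediction_gives_unit_cc(self, scripted):
        script, measured = scripted
        report = md.segment_and_score(
            measured.timestamps, measured.angles, measured, script
        )
        assert np.allclose(report.per_dof, 1.0)
        # every DOF that varies within a class scores exactly 1; constant
        # DOFs carry no correlation information and are skipped
        for ccs in report.per_class.values():
            defined = ccs[~np.isnan(ccs)]
            assert defined.size > 0 and np.allclose(defined, 1.0)

    def test_constant_offset_is_invisible_to_cc(self, scripted):
        script, measured = scripted
        report = md.segment_and_score(
            measured.timestamps, measured.angles + 4.2, measured, script
        )
        assert np.allclose(report.per_dof, 1.0)

    def test_class_segments_cover_each_entry_once(self, scripted):
        script, measured = scripted
        ts = measured.timestamps
        masks = {name: np.zeros(ts.size, dtype=bool) for name in md.MOTION_CLASSES}
        for motion, start, end in script.segment_times():
            for name, members in md.MOTION_CLASSES.items():
                if motion in members:
                    seg = (ts >= start) & (ts < end)
                    assert not np.any(masks[name] & seg)  # no double counting
                    masks[name] |= seg
        total = sum(m.sum() for m in masks.values())
        non_rest = sum(
            1 for motion, *_ in script.segment_times() if motion != "M0"
        )
        assert total == pytest.approx(non_rest * 2.0 * 120.0, rel=0.02)


class TestOneWayANOVA:
    def test_identical_groups_give_f_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = md.one_way_anova([g.copy(), g.copy(), g.copy()])
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0
        assert res.stable

    def test_separated_means_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 100)
        b = rng.normal(10, 1, 100)  # 10 within-group SDs apart
        res = md.one_way_anova([a, b])
        assert res.p_value < 1e-3
        assert not res.stable

    def test_matches_permutation_oracle(self):
        # F-test p-value vs label-permutation estimate on small groups
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 8), rng.normal(0.8, 1, 8), rng.normal(0.3, 1, 8)]
        res = md.one_way_anova(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]

        def f_of(perm):
            parts = np.split(pooled[perm], np.cumsum(sizes)[:-1])
            return stats.f_oneway(*parts)[0]

        n_perm = 2000
        count = 0
        for _ in range(n_perm):
            if f_of(rng.permutation(pooled.size)) >= res.f_statistic:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        # Monte-Carlo tolerance: 4 binomial SDs
        tol = 4 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p_value - p_perm) < max(tol, 0.02)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            md.one_way_anova([np.array([1.0])])


def scripted_tac_trajectory(targets, hold_s=0.6, travel_s=1.0, rate=50.0, total_s=32.0):
    """Trajectory that ramps to each target and holds; returns (ts, angles)."""
    ts = np.arange(int(total_s * rate)) / rate
    angles = np.zeros((ts.size, 3))
    t = 0.0
    prev = np.zeros(3)
    for target in targets:
        ramp = (ts >= t) & (ts < t + travel_s)
        frac = (ts[ramp] - t) / travel_s
        angles[ramp] = prev + frac[:, None] * (np.asarray(target) - prev)
        hold = ts >= t + travel_s
        angles[hold] = target
        prev = np.asarray(target, dtype=float)
        t += travel_s + hold_s
    return ts, angles


def brute_force_tac(ts, angles, config):
    """Independent oracle: per-sample in/out flags + run-length scan."""
    targets = np.asarray([t for _, t in config.postures])
    limit_t = ts[0] + config.trial_limit
    completions = []
    start = 0
    for p in range(len(targets)):
        inside = np.all(np.abs(angles - targets[p]) <= config.tolerance, axis=1)
        done = None
        run_start = None
        i = start
        while i < ts.size and ts[i] <= limit_t:
            if inside[i]:
                if run_start is None:
                    run_start = i
                if ts[i] - ts[run_start] >= config.dwell_time:
                    done = ts[i]
                    start = i
                    break
            else:
                run_start = None
            i += 1
        completions.append(done)
        if done is None:
            break
    # pad remaining postures as not achieved
    while len(completions) < len(targets):
        completions.append(None)
    return completions


class TestTACEvaluate:
    def test_scripted_trajectory_completes_all_postures(self):
        config = md.TACConfig.trial("TAC-1")
        ts, ang = scripted_tac_trajectory([t for _, t in config.postures])
        result = md.tac_evaluate((ts, ang), config)
        assert all(result.achieved)
        assert result.n_completed == 4
        # hand-simulated schedule: the trajectory starts at Central 1, so
        # the first posture completes exactly at the 0.5 s dwell mark;
        # later postures each add travel + dwell
        assert result.completion_times[0] == pytest.approx(0.5, abs=0.05)
        assert np.all(np.diff([t for t in result.completion_times]) > 0)

    def test_flat_zero_trajectory_times_out_after_first_posture(self):
        config = md.TACConfig.trial("TAC-1")
        ts = np.arange(0, 31.0, 0.02)
        ang = np.zeros((ts.size, 3))
        result = md.tac_evaluate((ts, ang), config)
        assert result.achieved == (True, False, False, False)
        assert result.n_completed == 1
        assert result.trial_end == pytest.approx(30.0, abs=0.1)

    def test_interrupted_dwell_does_not_complete(self):
        # 0.4 s inside, out, 0.4 s inside again: dwell must be continuous
        config = md.TACConfig.trial("TAC-1")
        rate = 100.0
        ts = np.arange(int(31 * rate)) / rate
        ang = np.zeros((ts.size, 3))
        target1 = np.array([15.0, 15.0, 15.0])
        # central posture completes around t = 0.5; then visit target 1 twice
        seg1 = (ts >= 1.0) & (ts < 1.4)
        seg2 = (ts >= 1.5) & (ts < 1.9)
        ang[seg1] = target1
        ang[seg2] = target1
        result = md.tac_evaluate((ts, ang), config)
        assert result.achieved[0]
        assert not result.achieved[1]

    def test_boundary_tolerance_is_closed(self):
        config = md.TACConfig.trial("TAC-1")
        ts = np.arange(0, 31.0, 0.02)
        ang = np.zeros((ts.size, 3))
        ang[ts >= 1.0] = [20.0, 20.0, 20.0]  # exactly target1 + tolerance
        result = md.tac_evaluate((ts, ang), config)
        assert result.achieved[1]

    def test_short_trajectory_without_timeout_raises(self):
        config = md.TACConfig.trial("TAC-1")
        ts = np.arange(0, 5.0, 0.02)
        ang = np.full((ts.size, 3), 100.0)
        with pytest.raises(TACEvaluationError):
            md.tac_evaluate((ts, ang), config)

    def test_matches_brute_force_oracle_on_random_trajectories(self):
        config = md.TACConfig.trial("TAC-1")
        rng = np.random.default_rng(0)
        for _ in range(100):
            ts = np.arange(0, 31.0, 0.05)
            # random walk wandering over the posture range
            steps = rng.normal(0, 2.0, size=(ts.size, 3))
            ang = np.cumsum(steps, axis=0)
            ang = np.clip(ang, -10, 40)
            result = md.tac_evaluate((ts, ang), config)
            oracle = brute_force_tac(ts, ang, config)
            got = [
                None if t is None else t for t in result.completion_times
            ]
            assert got == oracle


class TestCompletionRateCurve:
    @pytest.fixture()
    def config(self):
        return md.TACConfig.trial("TAC-1")

    def test_values_quantized_and_monotone(self, config):
        ts, ang = scripted_tac_trajectory([t for _, t in config.postures])
        result = md.tac_evaluate((ts, ang), config)
        bp, cr = md.completion_rate_curve(result, config)
        assert set(np.round(cr, 6)).issubset({0.0, 0.25, 0.5, 0.75, 1.0})
        assert np.all(np.diff(cr) >= 0)
        assert cr[0] == 0.0 and bp[0] == 0.0

    def test_half_completed(self, config):
        result = md.TACTrialResult(
            posture_names=("a", "b", "c", "d"),
            achieved=(True, True, False, False),
            completion_times=(1.0, 2.0, None, None),
            dwell_intervals=(None, None, None, None),
            trial_end=30.0,
        )
        bp, cr = md.completion_rate_curve(result, config)
        assert completion_rate_at(2.5, bp, cr) == 0.5

    def test_reaches_one_after_last_completion(self, config):
        ts, ang = scripted_tac_trajectory([t for _, t in config.postures])
        result = md.tac_evaluate((ts, ang), config)
        bp, cr = md.completion_rate_curve(result, config)
        t_star = max(t for t in result.completion_times)
        assert completion_rate_at(t_star, bp, cr) == 1.0
        assert completion_rate_at(30.0, bp, cr) == 1.0

    def test_timeout_trajectory_caps_at_quarter(self, config):
        ts = np.arange(0, 31.0, 0.02)
        result = md.tac_evaluate((ts, np.zeros((ts.size, 3))), config)
        bp, cr = md.completion_rate_curve(result, config)
        assert completion_rate_at(30.0, bp, cr) == 0.25


class TestANOVANullCalibration:
    def test_p_values_uniform_under_null(self):
        # 1000 null datasets of 5 x 30 samples: the ANOVA p-values must be
        # uniform on [0, 1] (Kolmogorov-Smirnov at alpha = 0.01)
        rng = np.random.default_rng(7)
        pvals = np.empty(1000)
        for i in range(1000):
            groups = [rng.normal(0, 1, 30) for _ in range(5)]
            pvals[i] = md.one_way_anova(groups).p_value
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
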