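"""Synthetic-data generator: trajectories, activations, EMG synthesis."""

import numpy as np
import pytest

import myodecode as md
from myodecode.synth import InvalidScriptError, activation_envelope


class TestMotionScript:
    def test_rejects_unknown_motion(self):
        with pytest.raises(InvalidScriptError):
            md.MotionScript.from_pairs([("M99", 1.0)])

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(InvalidScriptError):
            md.MotionScript.from_pairs([("M1", 0.0)])

    def test_segment_times_partition_duration(self):
        script = md.MotionScript.from_pairs([("M0", 1.0), ("M1", 2.5), ("M0", 0.5)])
        segs = script.segment_times()
        assert segs[0][1] == 0.0
        assert segs[-1][2] == pytest.approx(script.total_duration)
        for (_, _, e), (_, s, _) in zip(segs[:-1], segs[1:]):
            assert e == s


class TestRenderAngleTrajectory:
    def test_rest_renders_zero(self):
        script = md.MotionScript.from_pairs([("M0", 1.0)])
        stream = md.render_angle_trajectory(script, rate=120.0)
        assert stream.angles.shape == (120, 3)
        assert np.all(stream.angles == 0.0)

    def test_single_flexion_targets_dof1_only(self):
        # wrist flexion: positive DOF1 plateau, other DOFs untouched
        script = md.MotionScript.from_pairs([("M1", 1.0)])
        stream = md.render_angle_trajectory(script, rate=120.0, max_angle=30.0)
        plateau = stream.angles[60:]  # past the 0.3 s ramp
        assert np.all(plateau[:, 0] == pytest.approx(30.0))
        assert np.all(stream.angles[:, 1] == 0.0)
        assert np.all(stream.angles[:, 2] == 0.0)

    def test_deterministic(self):
        script = md.MotionScript.from_pairs([("M1", 1.0), ("M7", 2.0)])
        a = md.render_angle_trajectory(script)
        b = md.render_angle_trajectory(script)
        assert np.array_equal(a.angles, b.angles)
        assert np.array_equal(a.timestamps, b.timestamps)

    def test_starts_and_ends_at_rest_for_m0_bracketed_script(self):
        script = md.MotionScript.from_pairs([("M0", 1.0), ("M13", 2.0), ("M0", 1.0)])
        stream = md.render_angle_trajectory(script)
        assert np.all(stream.angles[0] == 0.0)
        # final M0 segment has settled back to rest after its ramp
        assert np.allclose(stream.angles[-1], 0.0, atol=1e-9)

    def test_ramps_are_continuous(self):
        script = md.MotionScript.from_pairs([("M0", 0.5), ("M1", 1.0), ("M2", 1.0)])
        stream = md.render_angle_trajectory(script, rate=500.0)
        steps = np.abs(np.diff(stream.angles, axis=0)).max()
        # 60 deg swing over 0.3 s at 500 Hz: per-sample step bounded by
        # max slope of the cosine ramp, pi/2 * 60/0.3 / 500 ~ 0.63 deg
        assert steps < 1.0

    @pytest.mark.parametrize("motion,expected_sign", [
        ("M1", (1, 0, 0)), ("M2", (-1, 0, 0)), ("M3", (0, 1, 0)),
        ("M4", (0, -1, 0)), ("M5", (0, 0, 1)), ("M11", (-1, 1, 1)),
    ])
    def test_plateau_signs_match_motion_table(self, motion, expected_sign):
        script = md.MotionScript.from_pairs([(motion, 1.0)])
        stream = md.render_angle_trajectory(script, max_angle=30.0)
        plateau = stream.angles[-1]
        for d, sign in enumerate(expected_sign):
            assert np.sign(plateau[d]) == sign


class TestAnglesToActivations:
    def test_zero_angles_zero_activations(self):
        act = md.angles_to_activations(np.zeros((10, 3)))
        assert np.all(act == 0.0)

    def test_saturation_at_max_angle(self):
        angles = np.array([[30.0, 0.0, 0.0]])
        act = md.angles_to_activations(angles, max_angle=30.0)
        assert act[0, 0] == 1.0  # agonist DOF1
        assert act[0, 1] == 0.0  # antagonist DOF1

    def test_negative_half_excursion_drives_antagonist(self):
        # DOF2 at -max/2: antagonist2 at exactly 0.5, agonist2 silent
        angles = np.array([[0.0, -15.0, 0.0]])
        act = md.angles_to_activations(angles, max_angle=30.0)
        assert act[0, 3] == pytest.approx(0.5)
        assert act[0, 2] == 0.0

    def test_all_nonnegative(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(-60, 60, size=(50, 3))
        angles[:, 2] = np.abs(angles[:, 2])
        assert np.all(md.angles_to_activations(angles) >= 0.0)


class TestSynthesizeEMG:
    def test_requires_seed(self):
        syn = md.default_synergy_model(0)
        with pytest.raises(ValueError, match="seed"):
            md.synthesize_emg(np.zeros((10, 6)), syn, seed=None)

    def test_same_seed_bit_identical(self, synergy):
        act = np.random.default_rng(0).uniform(0, 1, size=(100, 6))
        a = md.synthesize_emg(act, synergy, seed=5)
        b = md.synthesize_emg(act, synergy, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_zero_activation_std_matches_baseline(self, synergy):
        # Monte-Carlo: with all muscles silent the per-channel standard
        # deviation equals the baseline envelope amplitude
        n = 20000
        stream = md.synthesize_emg(np.zeros((n, 6)), synergy, seed=11)
        stds = stream.samples.std(axis=0)
        assert np.allclose(stds, synergy.baseline_noise, rtol=0.05)

    def test_envelope_superposition(self, synergy):
        # the noise-free envelope is linear in activations
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, size=(50, 6))
        b = rng.uniform(0, 1, size=(50, 6))
        base = synergy.baseline_noise
        lhs = activation_envelope(a + b, synergy) - base
        rhs = (activation_envelope(a, synergy) - base) + (
            activation_envelope(b, synergy) - base
        )
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-14)

    def test_doubling_activation_doubles_envelope_contribution(self, synergy):
        act = np.zeros((10, 6))
        act[:, 2] = 0.4
        act2 = 2.0 * act
        delta1 = activation_envelope(act, synergy) - synergy.baseline_noise
        delta2 = activation_envelope(act2, synergy) - synergy.baseline_noise
        assert np.allclose(delta2, 2.0 * delta1, rtol=1e-12)


class TestSynthesizeMVC:
    def test_shape_and_rate(self, synergy):
        mvc = md.synthesize_mvc(synergy, duration=4.0, seed=1)
        assert mvc.samples.shape == (2000, 32)
        assert mvc.rate == 500.0

    def test_plateau_envelope_is_mixing_rowsum_plus_baseline(self, synergy):
        # at full simultaneous activation the envelope per channel is the
        # row-sum of the mixing matrix plus baseline
        ones = np.ones((10, 6))
        env = activation_envelope(ones, synergy)
        expected = synergy.mixing.sum(axis=1) + synergy.baseline_noise
        assert np.allclose(env, expected[None, :])

    def test_seeded_determinism(self, synergy):
        a = md.synthesize_mvc(synergy, duration=4.0, seed=3)
        b = md.synthesize_mvc(synergy, duration=4.0, seed=3)
        assert np.array_equal(a.samples, b.samples)


class TestRestEnvelopeStatistics:
    def test_rest_rectified_mean_matches_baseline(self, synergy):
        # rectified-mean estimate of a rest segment: E|N(0, sigma)| with
        # sigma = baseline_noise, so mean(|x|) = baseline * sqrt(2/pi)
        n = 20000
        stream = md.synthesize_emg(np.zeros((n, 6)), synergy, seed=21)
        rect_mean = np.abs(stream.samples).mean(axis=0)
        expected = synergy.baseline_noise * np.sqrt(2.0 / np.pi)
        assert np.allclose(rect_mean, expected, rtol=0.05)


class TestSynergyModelValidation:
    def test_rejects_negative_mixing(self):
        m = np.ones((32, 6))
        m[0, 0] = -0.1
        with pytest.raises(ValueError, match="nonnegative"):
            md.SynergyModel(mixing=m)

    def test_rejects_silent_muscle(self):
        m = np.ones((32, 6))
        m[:, 4] = 0.0
        with pytest.raises(ValueError, match="at least one channel"):
            md.SynergyModel(mixing=m)
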