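"""Synthetic sEMG, MVC, and ground-truth angle generation.

Emulates a 32-channel surface-EMG sleeve recording at 500 Hz together with a
motion-capture angle stream at 120 Hz, driven by scripted wrist/hand motions.
Each of the three degrees of freedom (DOF1 wrist flexion/extension, DOF2
pronation/supination, DOF3 hand grip) is actuated by an agonist/antagonist
pair of virtual muscles; a nonnegative synergy mixing matrix maps the six
muscle activations to per-channel EMG envelopes, and the raw signal is a
zero-mean white-noise carrier amplitude-modulated by that envelope.

The generator is deliberately simple: the downstream pipeline only consumes
the rectified-filtered envelope, so carrier spectral shape is irrelevant to
pipeline correctness and is left white.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MOTION_TARGETS",
    "MOTION_CLASSES",
    "MotionScript",
    "SynergyModel",
    "AngleStream",
    "RawEMGStream",
    "default_synergy_model",
    "render_angle_trajectory",
    "render_posture_sequence",
    "angles_to_activations",
    "activation_envelope",
    "synthesize_emg",
    "synthesize_mvc",
    "simulate_session",
]

N_CHANNELS = 32
N_MUSCLES = 6  # agonist/antagonist per DOF
EMG_RATE = 500.0
ANGLE_RATE = 120.0

#: Signed target amplitude per DOF (fraction of max_angle) for each motion.
#: DOF1: flexion +, extension -.  DOF2: pronation +, supination -.
#: DOF3: grip, nonnegative.
MOTION_TARGETS: dict[str, tuple[float, float, float]] = {
    "M0": (0.0, 0.0, 0.0),    # rest
    "M1": (1.0, 0.0, 0.0),    # wrist flexion
    "M2": (-1.0, 0.0, 0.0),   # wrist extension
    "M3": (0.0, 1.0, 0.0),    # wrist pronation
    "M4": (0.0, -1.0, 0.0),   # wrist supination
    "M5": (0.0, 0.0, 1.0),    # hand grip
    "M6": (1.0, 0.0, 1.0),    # WF + HG
    "M7": (-1.0, 0.0, 1.0),   # WE + HG
    "M8": (0.0, 1.0, 1.0),    # WP + HG
    "M9": (0.0, -1.0, 1.0),   # WS + HG
    "M10": (1.0, 1.0, 1.0),   # WF + WP + HG
    "M11": (-1.0, 1.0, 1.0),  # WE + WP + HG
    "M12": (1.0, -1.0, 1.0),  # WF + WS + HG
    "M13": (-1.0, -1.0, 1.0), # WE + WS + HG
}

#: Motion classes used when scoring per movement type.
MOTION_CLASSES: dict[str, tuple[str, ...]] = {
    "single": ("M1", "M2", "M3", "M4", "M5"),
    "double": ("M6", "M7", "M8", "M9"),
    "triple": ("M10", "M11", "M12", "M13"),
}


class InvalidScriptError(ValueError):
    """Raised when a motion script references unknown motions or bad durations."""


@dataclass(frozen=True)
class MotionScript:
    """Ordered sequence of (motion_id, duration_seconds) entries."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise InvalidScriptError("script has no entries")
        for motion, duration in self.entries:
            if motion not in MOTION_TARGETS:
                raise InvalidScriptError(f"unknown motion id {motion!r}")
            if not (duration > 0 and np.isfinite(duration)):
                raise InvalidScriptError(
                    f"duration for {motion} must be positive and finite, got {duration}"
                )

    @classmethod
    def from_pairs(cls, pairs) -> "MotionScript":
        return cls(tuple((str(m), float(d)) for m, d in pairs))

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.entries))

    def segment_times(self) -> list[tuple[str, float, float]]:
        """(motion_id, start_s, end_s) for each entry."""
        out, t = [], 0.0
        for motion, duration in self.entries:
            out.append((motion, t, t + duration))
            t += duration
        return out


def standard_trial_script(
    motion_duration: float = 3.0, rest_duration: float = 1.5
) -> MotionScript:
    """One trial: rest, then M1..M13 each separated by rest, ending at rest."""
    pairs: list[tuple[str, float]] = [("M0", rest_duration)]
    for k in range(1, 14):
        pairs.append((f"M{k}", motion_duration))
        pairs.append(("M0", rest_duration))
    return MotionScript.from_pairs(pairs)


@dataclass(frozen=True)
class SynergyModel:
    """Maps 6 virtual muscle activations to 32 per-channel envelope gains.

    mixing[c, j] >= 0 is the gain from muscle j to channel c; baseline_noise
    is the envelope floor present even at rest (sensor/physiological noise).
    """

    mixing: np.ndarray  # (32, 6), nonnegative
    baseline_noise: float = 0.05
    carrier_seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.mixing, dtype=float)
        if m.shape != (N_CHANNELS, N_MUSCLES):
            raise ValueError(f"mixing must be ({N_CHANNELS}, {N_MUSCLES}), got {m.shape}")
        if np.any(m < 0):
            raise ValueError("mixing entries must be nonnegative")
        if np.any(m.sum(axis=0) == 0):
            raise ValueError("every virtual muscle must drive at least one channel")
        if self.baseline_noise < 0:
            raise ValueError("baseline_noise must be nonnegative")
        object.__setattr__(self, "mixing", m)


def default_synergy_model(
    seed: int = 0, baseline_noise: float = 0.05, crosstalk: float = 0.15
) -> SynergyModel:
    """Block-structured mixing: each muscle dominates a band of electrodes,
    with mild random crosstalk everywhere (electrodes see neighbouring
    muscles through the volume conductor)."""
    rng = np.random.default_rng(seed)
    mixing = rng.uniform(0.0, crosstalk, size=(N_CHANNELS, N_MUSCLES))
    # 32 channels / 6 muscles: bands of 5-6 channels each
    bounds = np.linspace(0, N_CHANNELS, N_MUSCLES + 1).astype(int)
    for j in range(N_MUSCLES):
        lo, hi = bounds[j], bounds[j + 1]
        mixing[lo:hi, j] += rng.uniform(0.6, 1.0, size=hi - lo)
    return SynergyModel(mixing=mixing, baseline_noise=baseline_noise, carrier_seed=seed)


def perturbed_synergy_model(
    base: SynergyModel, seed: int, scale: float = 0.35, channel_shift: int = 2
) -> SynergyModel:
    """Day-two variant of a synergy model.

    Emulates re-donning the electrode sleeve on another day: the sleeve sits
    rotated by a couple of electrode positions (cyclic shift of the channel
    rows) and per-channel gains drift multiplicatively (skin impedance).
    The muscle-to-envelope temporal structure is unchanged — which is why
    freezing the temporal filters and retraining only the channel-mixing
    fully connected layer recovers performance.
    """
    rng = np.random.default_rng(seed)
    drift = rng.uniform(1.0 - scale, 1.0 + scale, size=base.mixing.shape)
    mixing = np.roll(base.mixing, channel_shift, axis=0) * drift
    return SynergyModel(
        mixing=mixing,
        baseline_noise=base.baseline_noise,
        carrier_seed=seed,
    )


@dataclass(frozen=True)
class AngleStream:
    """Timestamped 3-DOF joint-angle series in degrees."""

    timestamps: np.ndarray  # (N,), seconds, strictly increasing
    angles: np.ndarray      # (N, 3), degrees
    rate: float

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        ang = np.asarray(self.angles, dtype=float)
        if ts.ndim != 1 or ang.shape != (ts.size, 3):
            raise ValueError("timestamps must be (N,) and angles (N, 3)")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(ang[:, 2] < -1e-9):
            raise ValueError("DOF3 (grip) angles must be nonnegative")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "angles", ang)


@dataclass(frozen=True)
class RawEMGStream:
    """Timestamped multichannel raw sEMG series (arbitrary units)."""

    timestamps: np.ndarray  # (M,), seconds, strictly increasing
    samples: np.ndarray     # (M, 32)
    rate: float

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        s = np.asarray(self.samples, dtype=float)
        if ts.ndim != 1 or s.ndim != 2 or s.shape[0] != ts.size:
            raise ValueError("timestamps must be (M,) and samples (M, C)")
        if s.shape[1] != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels, got {s.shape[1]}")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "samples", s)


def render_angle_trajectory(
    script: MotionScript,
    rate: float = ANGLE_RATE,
    max_angle: float = 30.0,
    ramp_s: float = 0.3,
) -> AngleStream:
    """Render a motion script to a 3-DOF angle trajectory.

    Each entry holds its target posture as a plateau; transitions between
    consecutive plateaus use a cosine ramp of ``ramp_s`` seconds (clipped to
    the entry duration) so "measured" angles have no step discontinuities.
    """
    if not rate > 0:
        raise ValueError("rate must be positive")
    n = int(round(script.total_duration * rate))
    t = np.arange(n) / rate
    angles = np.empty((n, 3))
    prev_target = np.zeros(3)  # scripts implicitly start from rest posture
    for motion, start, end in script.segment_times():
        target = max_angle * np.asarray(MOTION_TARGETS[motion])
        mask = (t >= start) & (t < end)
        seg_t = t[mask] - start
        ramp = min(ramp_s, end - start)
        blend = np.ones_like(seg_t)
        if ramp > 0:
            in_ramp = seg_t < ramp
            blend[in_ramp] = 0.5 * (1.0 - np.cos(np.pi * seg_t[in_ramp] / ramp))
        angles[mask] = prev_target + blend[:, None] * (target - prev_target)
        prev_target = target
    return AngleStream(timestamps=t, angles=angles, rate=rate)


def render_posture_sequence(
    targets,
    hold_s: float = 2.0,
    travel_s: float = 1.0,
    rate: float = ANGLE_RATE,
    lead_s: float = 0.5,
    min_total_s: float | None = None,
) -> AngleStream:
    """Render a trajectory that visits arbitrary 3-DOF postures in order.

    Starts at the first posture (after a short lead hold), then cosine-ramps
    to each subsequent target over ``travel_s`` and holds it ``hold_s`` —
    the ground-truth motion of a TAC-style reaching task.  The final posture
    is held longer if needed to reach ``min_total_s``.
    """
    targets = [np.asarray(t, dtype=float) for t in targets]
    duration = lead_s + hold_s + (len(targets) - 1) * (travel_s + hold_s)
    if min_total_s is not None:
        duration = max(duration, min_total_s)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    angles = np.empty((n, 3))
    angles[:] = targets[0]
    seg_start = lead_s + hold_s
    prev = targets[0]
    for target in targets[1:]:
        ramp = (t >= seg_start) & (t < seg_start + travel_s)
        frac = (t[ramp] - seg_start) / travel_s
        blend = 0.5 * (1.0 - np.cos(np.pi * frac))
        angles[ramp] = prev + blend[:, None] * (target - prev)
        angles[t >= seg_start + travel_s] = target
        prev = target
        seg_start += travel_s + hold_s
    return AngleStream(timestamps=t, angles=angles, rate=rate)


def angles_to_activations(angles: np.ndarray, max_angle: float = 30.0) -> np.ndarray:
    """Map (N, 3) angles to (N, 6) nonnegative virtual-muscle activations.

    Per DOF, positive excursion drives the agonist, negative the antagonist,
    both rectified-linear in the angle and saturating at ``max_angle``.
    Column order: [ag1, ant1, ag2, ant2, ag3, ant3].
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("angles must be (N, 3)")
    scaled = a / max_angle
    act = np.empty((a.shape[0], N_MUSCLES))
    for d in range(3):
        act[:, 2 * d] = np.clip(scaled[:, d], 0.0, 1.0)
        act[:, 2 * d + 1] = np.clip(-scaled[:, d], 0.0, 1.0)
    return act


def activation_envelope(activations: np.ndarray, model: SynergyModel) -> np.ndarray:
    """Noise-free per-channel envelope: mixing @ activation + baseline.

    Exactly linear in the activations (superposition holds bit-exactly);
    the stochastic carrier multiplies this envelope in synthesize_emg.
    """
    act = np.asarray(activations, dtype=float)
    if act.ndim != 2 or act.shape[1] != N_MUSCLES:
        raise ValueError(f"activations must be (N, {N_MUSCLES})")
    return act @ model.mixing.T + model.baseline_noise


def synthesize_emg(
    activations: np.ndarray,
    model: SynergyModel,
    rate: float = EMG_RATE,
    seed: int | None = None,
    t0: float = 0.0,
) -> RawEMGStream:
    """Amplitude-modulate a seeded zero-mean unit-variance white carrier by
    the synergy envelope: samples[t, c] = carrier[t, c] * envelope[t, c]."""
    if seed is None:
        raise ValueError("seed is required for reproducible synthesis")
    env = activation_envelope(activations, model)
    rng = np.random.default_rng(seed)
    carrier = rng.standard_normal(env.shape)
    ts = t0 + np.arange(env.shape[0]) / rate
    return RawEMGStream(timestamps=ts, samples=carrier * env, rate=rate)


def synthesize_mvc(
    model: SynergyModel,
    duration: float = 5.0,
    seed: int = 0,
    rate: float = EMG_RATE,
    rest_s: float = 1.0,
    ramp_s: float = 0.3,
) -> RawEMGStream:
    """Maximum-voluntary-contraction burst recording.

    Rest, then a plateau with all six virtual muscles at full activation
    simultaneously, then rest again (cosine on/off ramps).  The plateau
    gives each channel its maximal envelope (row-sum of mixing + baseline)
    and the rest phases give the minimal envelope (baseline), which are the
    two anchors the min-max normalizer keys on.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if duration <= 2 * (rest_s + ramp_s):
        raise ValueError("duration too short for rest/ramp phases")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    level = np.zeros(n)
    up, down = rest_s, duration - rest_s
    rising = (t >= up) & (t < up + ramp_s)
    level[rising] = 0.5 * (1.0 - np.cos(np.pi * (t[rising] - up) / ramp_s))
    level[(t >= up + ramp_s) & (t < down - ramp_s)] = 1.0
    falling = (t >= down - ramp_s) & (t < down)
    level[falling] = 0.5 * (1.0 + np.cos(np.pi * (t[falling] - (down - ramp_s)) / ramp_s))
    activations = np.repeat(level[:, None], N_MUSCLES, axis=1)
    return synthesize_emg(activations, model, rate=rate, seed=seed)


def simulate_session(
    script: MotionScript,
    model: SynergyModel,
    seed: int,
    max_angle: float = 30.0,
    emg_rate: float = EMG_RATE,
    angle_rate: float = ANGLE_RATE,
) -> tuple[AngleStream, RawEMGStream]:
    """Render one scripted session: the "measured" angle stream at the
    motion-capture rate and the raw EMG stream at the acquisition rate,
    both driven by the same underlying trajectory."""
    angle_stream = render_angle_trajectory(script, rate=angle_rate, max_angle=max_angle)
    dense = render_angle_trajectory(script, rate=emg_rate, max_angle=max_angle)
    activations = angles_to_activations(dense.angles, max_angle=max_angle)
    emg_stream = synthesize_emg(activations, model, rate=emg_rate, seed=seed)
    return angle_stream, emg_stream
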