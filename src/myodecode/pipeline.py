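"""Session-level convenience workflows tying the modules together.

These are the offline counterparts of the real-time engine: batch-normalize
a whole recording, build supervised training sets from scripted trials, and
run the two-day initial-training / layer-transfer experiment on synthetic
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CVReport,
    CWCNNParams,
    TrainingConfig,
    forward_batch,
    layer_transfer,
    pair_and_resample,
    train_initial,
)
from .processing import (
    FIRSpec,
    FilterState,
    MVCProfile,
    compute_mvc_profile,
    default_fir,
    fir_filter,
    normalize_iemg,
    rectify,
)
from .synth import (
    MotionScript,
    RawEMGStream,
    SynergyModel,
    default_synergy_model,
    perturbed_synergy_model,
    simulate_session,
    standard_trial_script,
    synthesize_mvc,
)

__all__ = [
    "preprocess_stream",
    "build_training_set",
    "session_cc",
    "TwoDayExperimentResult",
    "run_two_day_experiment",
]


def preprocess_stream(
    emg: RawEMGStream, profile: MVCProfile, fir: FIRSpec
) -> np.ndarray:
    """Whole-recording rectify -> FIR -> MVC-normalize (cold-start filter)."""
    state = FilterState.cold_start(fir, channels=emg.samples.shape[1])
    filtered, _ = fir_filter(rectify(emg.samples), fir, state)
    return normalize_iemg(filtered, profile)


def build_training_set(
    script: MotionScript,
    synergy: SynergyModel,
    profile: MVCProfile,
    fir: FIRSpec,
    seeds,
    stride: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one scripted trial per seed and assemble supervised pairs.

    Returns (windows, targets, trial_groups) ready for trial-grouped CV.
    """
    xs, ys, gs = [], [], []
    for i, seed in enumerate(seeds):
        angles, emg = simulate_session(script, synergy, seed=int(seed))
        norm = preprocess_stream(emg, profile, fir)
        x, y = pair_and_resample(emg.timestamps, norm, angles, stride=stride)
        xs.append(x)
        ys.append(y)
        gs.append(np.full(len(x), i))
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(gs)


def session_cc(params: CWCNNParams, windows: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-DOF Pearson CC of a model's predictions on a labeled set."""
    pred = forward_batch(params, windows)
    out = np.empty(targets.shape[1])
    for d in range(targets.shape[1]):
        p, t = pred[:, d], targets[:, d]
        out[d] = np.mean((p - p.mean()) * (t - t.mean())) / (p.std() * t.std())
    return out


@dataclass(frozen=True)
class TwoDayExperimentResult:
    """Outcome of the initial-training + layer-transfer experiment."""

    initial_params: CWCNNParams
    initial_report: CVReport
    transferred_params: CWCNNParams
    transfer_report: CVReport
    stale_cc: np.ndarray        # day-1 model evaluated on held-out day-2 data
    transferred_cc: np.ndarray  # transferred model on the same held-out data
    synergy_day1: SynergyModel
    synergy_day2: SynergyModel
    profile_day1: MVCProfile
    profile_day2: MVCProfile
    fir: FIRSpec
    script: MotionScript


def run_two_day_experiment(
    seed: int = 0,
    n_initial_trials: int = 10,
    n_transfer_trials: int = 5,
    motion_duration: float = 2.0,
    rest_duration: float = 1.0,
    initial_config: TrainingConfig | None = None,
    transfer_config: TrainingConfig | None = None,
) -> TwoDayExperimentResult:
    """Synthetic two-day protocol.

    Day 1: ``n_initial_trials`` scripted trials from a known synergy model;
    initial training with trial-grouped 10-fold CV.  Day 2: the synergy
    model is perturbed (sleeve rotation + gain drift), a fresh MVC is
    recorded, ``n_transfer_trials`` new trials retrain the fully connected
    layer with the convolutional layer frozen (5-fold CV).  Both the stale
    day-1 model and the transferred model are scored on a held-out day-2
    trial.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    script = standard_trial_script(motion_duration, rest_duration)
    fir = default_fir()

    synergy1 = default_synergy_model(sub())
    profile1 = compute_mvc_profile(synthesize_mvc(synergy1, 5.0, seed=sub()), fir)
    x1, y1, g1 = build_training_set(
        script, synergy1, profile1, fir, [sub() for _ in range(n_initial_trials)]
    )
    cfg1 = initial_config or TrainingConfig(folds=10, seed=seed)
    params1, report1 = train_initial(x1, y1, cfg1, groups=g1)

    synergy2 = perturbed_synergy_model(synergy1, seed=sub())
    profile2 = compute_mvc_profile(synthesize_mvc(synergy2, 5.0, seed=sub()), fir)
    x2, y2, g2 = build_training_set(
        script, synergy2, profile2, fir, [sub() for _ in range(n_transfer_trials)]
    )
    cfg2 = transfer_config or TrainingConfig(folds=5, seed=seed + 1)
    params2, report2 = layer_transfer(params1, x2, y2, cfg2, groups=g2)

    xh, yh, _ = build_training_set(script, synergy2, profile2, fir, [sub()])
    return TwoDayExperimentResult(
        initial_params=params1,
        initial_report=report1,
        transferred_params=params2,
        transfer_report=report2,
        stale_cc=session_cc(params1, xh, yh),
        transferred_cc=session_cc(params2, xh, yh),
        synergy_day1=synergy1,
        synergy_day2=synergy2,
        profile_day1=profile1,
        profile_day2=profile2,
        fir=fir,
        script=script,
    )
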