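"""Evaluation of decoded joint-angle streams.

Three instruments:

* Pearson correlation coefficient (CC) between predicted and measured
  angles, per DOF and per motion class (single / double-mixture /
  triple-mixture motions).
* One-way ANOVA across per-minute latency groups; the real-time system is
  declared temporally stable when p > 0.5 (a deliberately strict
  no-difference criterion: the groups must look indistinguishable).
* The target achievement control (TAC) test: a scripted sequence of target
  postures must each be reached within +/-5 deg on all three DOFs
  simultaneously and held continuously for 0.5 s, within a 30 s trial
  limit; summarized by the completion-rate curve CR(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synth import MOTION_CLASSES, AngleStream, MotionScript

__all__ = [
    "CCReport",
    "LatencyANOVA",
    "TACConfig",
    "TACTrialResult",
    "TAC_TABLES",
    "pearson_cc",
    "segment_and_score",
    "one_way_anova",
    "tac_evaluate",
    "completion_rate_curve",
]

N_DOF = 3


class UndefinedCCError(ValueError):
    """Raised when a correlation is requested on a zero-variance series."""


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length series.

    Computed as (1/(N-1)) * sum(((x - mx)/sx) * ((y - my)/sy)) with sample
    (N-1) standard deviations; always in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise UndefinedCCError("zero-variance series has undefined CC")
    cc = np.sum((x - x.mean()) / sx * ((y - y.mean()) / sy)) / (n - 1)
    return float(np.clip(cc, -1.0, 1.0))


@dataclass(frozen=True)
class CCReport:
    """Correlation summary of one decoded session."""

    per_dof: np.ndarray                      # (3,) CC over the whole session
    per_class: dict[str, np.ndarray]         # class -> (3,) per-DOF CC
    per_class_mean: dict[str, float]         # class -> CC averaged over DOFs

    def __post_init__(self) -> None:
        if np.any(np.abs(self.per_dof) > 1 + 1e-12):
            raise ValueError("CC values must lie in [-1, 1]")


def _resample_to(
    target_ts: np.ndarray, source_ts: np.ndarray, source_vals: np.ndarray
) -> np.ndarray:
    """Linear interpolation of (N, D) values onto new timestamps."""
    return np.column_stack(
        [np.interp(target_ts, source_ts, source_vals[:, d]) for d in range(source_vals.shape[1])]
    )


def segment_and_score(
    pred_timestamps: np.ndarray,
    pred_angles: np.ndarray,
    measured: AngleStream,
    script: MotionScript,
) -> CCReport:
    """CC per DOF over the whole session and per motion class.

    The measured (120 Hz) stream is interpolated onto the prediction
    timestamps.  Class segments are the script entries belonging to each
    motion class, concatenated; every non-rest entry is counted exactly once.
    """
    ts = np.asarray(pred_timestamps, dtype=float)
    pred = np.asarray(pred_angles, dtype=float)
    if pred.shape != (ts.size, N_DOF):
        raise ValueError("predictions must be (N, 3) aligned with timestamps")
    if ts[0] < measured.timestamps[0] - 1e-9 or ts[-1] > measured.timestamps[-1] + 1e-9:
        raise ValueError("prediction timestamps extend beyond the measured stream")
    truth = _resample_to(ts, measured.timestamps, measured.angles)

    per_dof = np.empty(N_DOF)
    for d in range(N_DOF):
        try:
            per_dof[d] = pearson_cc(pred[:, d], truth[:, d])
        except UndefinedCCError:
            # a script that never drives this DOF leaves the truth constant
            per_dof[d] = np.nan

    class_masks: dict[str, np.ndarray] = {
        name: np.zeros(ts.size, dtype=bool) for name in MOTION_CLASSES
    }
    for motion, start, end in script.segment_times():
        for name, members in MOTION_CLASSES.items():
            if motion in members:
                class_masks[name] |= (ts >= start) & (ts < end)
    class_masks["all"] = np.ones(ts.size, dtype=bool)

    per_class: dict[str, np.ndarray] = {}
    per_class_mean: dict[str, float] = {}
    for name, mask in class_masks.items():
        if mask.sum() < 2:
            continue
        ccs = np.empty(N_DOF)
        for d in range(N_DOF):
            try:
                ccs[d] = pearson_cc(pred[mask, d], truth[mask, d])
            except UndefinedCCError:
                # a DOF can be legitimately constant within a motion class
                # (e.g. grip during wrist-only motions on a noiseless
                # trajectory); it carries no correlation information
                ccs[d] = np.nan
        per_class[name] = ccs
        per_class_mean[name] = float(np.nanmean(ccs))
    return CCReport(per_dof=per_dof, per_class=per_class, per_class_mean=per_class_mean)


@dataclass(frozen=True)
class LatencyANOVA:
    """One-way ANOVA summary over latency groups."""

    group_means: np.ndarray
    group_vars: np.ndarray
    f_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def groups(self) -> int:
        return self.group_means.size

    @property
    def stable(self) -> bool:
        """No significant between-group difference at the p > 0.5 criterion."""
        return self.p_value > 0.5


def one_way_anova(groups: list[np.ndarray]) -> LatencyANOVA:
    """Classical one-way ANOVA (between/within decomposition) over groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    f_stat, p = stats.f_oneway(*arrays)
    if np.isnan(f_stat):  # all values identical across groups
        f_stat, p = 0.0, 1.0
    return LatencyANOVA(
        group_means=np.array([a.mean() for a in arrays]),
        group_vars=np.array([a.var(ddof=1) for a in arrays]),
        f_statistic=float(f_stat),
        p_value=float(p),
    )


def split_into_minutes(
    timestamps: np.ndarray, values: np.ndarray, minutes: int = 5
) -> list[np.ndarray]:
    """Partition a timed series into per-minute groups for the stability check."""
    ts = np.asarray(timestamps, dtype=float)
    vals = np.asarray(values, dtype=float)
    t0 = ts[0]
    return [
        vals[(ts - t0 >= 60.0 * m) & (ts - t0 < 60.0 * (m + 1))] for m in range(minutes)
    ]


#: Target-posture tables for the three TAC trials: each trial runs
#: Central 1 -> Target 1 -> Target 2 -> Central 2 (4 postures).
TAC_TABLES: dict[str, tuple[tuple[str, tuple[float, float, float]], ...]] = {
    "TAC-1": (
        ("Central 1", (0.0, 0.0, 0.0)),
        ("Target 1", (15.0, 15.0, 15.0)),
        ("Target 2", (30.0, 30.0, 30.0)),
        ("Central 2", (0.0, 0.0, 0.0)),
    ),
    "TAC-2": (
        ("Central 1", (0.0, 0.0, 0.0)),
        ("Target 1", (-15.0, 15.0, 15.0)),
        ("Target 2", (-30.0, 30.0, 30.0)),
        ("Central 2", (0.0, 0.0, 0.0)),
    ),
    "TAC-3": (
        ("Central 1", (0.0, 0.0, 0.0)),
        ("Target 1", (15.0, -15.0, 15.0)),
        ("Target 2", (30.0, -30.0, 30.0)),
        ("Central 2", (0.0, 0.0, 0.0)),
    ),
}


@dataclass(frozen=True)
class TACConfig:
    """TAC-test parameters: dwell 0.5 s, tolerance +/-5 deg, limit 30 s."""

    postures: tuple[tuple[str, tuple[float, float, float]], ...]
    dwell_time: float = 0.5
    tolerance: float = 5.0
    trial_limit: float = 30.0
    dof_count: int = 3

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if not self.dwell_time < self.trial_limit:
            raise ValueError("dwell_time must be below the trial limit")
        if not self.postures:
            raise ValueError("posture list is empty")

    @classmethod
    def trial(cls, name: str, **kwargs) -> "TACConfig":
        return cls(postures=TAC_TABLES[name], **kwargs)

    @property
    def n_postures(self) -> int:
        return len(self.postures)


@dataclass(frozen=True)
class TACTrialResult:
    """Posture-by-posture outcome of one TAC trial."""

    posture_names: tuple[str, ...]
    achieved: tuple[bool, ...]
    completion_times: tuple[float | None, ...]  # None on timeout
    dwell_intervals: tuple[tuple[float, float] | None, ...]
    trial_end: float

    def __post_init__(self) -> None:
        done = [t for t in self.completion_times if t is not None]
        if any(b > a for a, b in zip(done[1:], done[:-1])):
            raise ValueError("completion times must be nondecreasing")

    @property
    def n_completed(self) -> int:
        return sum(self.achieved)


class TACEvaluationError(RuntimeError):
    pass


def tac_evaluate(trajectory, config: TACConfig) -> TACTrialResult:
    """Run the TAC state machine over a decoded 3-DOF trajectory.

    ``trajectory`` is an AngleStream or any (timestamps, angles) pair —
    decoded trajectories may transiently leave the physical angle range, so
    no ground-truth invariants are imposed here.

    A posture is achieved when |angle_d - target_d| <= tolerance on all
    DOFs simultaneously (closed interval), held CONTINUOUSLY for the dwell
    time; any excursion resets the dwell clock.  Postures advance in order;
    the trial ends at the final posture's completion or at the time limit.
    Dwell timing uses the trajectory's own timestamps, so irregular output
    rates are handled naturally.  Evaluation of posture j+1 starts at the
    sample where posture j completed.
    """
    if hasattr(trajectory, "timestamps"):
        ts, ang = trajectory.timestamps, trajectory.angles
    else:
        ts, ang = trajectory
    ts = np.asarray(ts, dtype=float)
    ang = np.asarray(ang, dtype=float)
    duration = ts[-1] - ts[0]
    names = tuple(n for n, _ in config.postures)
    targets = np.asarray([t for _, t in config.postures])

    achieved: list[bool] = []
    times: list[float | None] = []
    dwells: list[tuple[float, float] | None] = []
    t0 = ts[0]
    limit_t = t0 + config.trial_limit
    start_idx = 0
    timed_out = False
    for p in range(len(names)):
        inside = np.all(np.abs(ang - targets[p]) <= config.tolerance, axis=1)
        completed_at: float | None = None
        dwell: tuple[float, float] | None = None
        if not timed_out:
            dwell_start: float | None = None
            for i in range(start_idx, ts.size):
                if ts[i] > limit_t:
                    break
                if inside[i]:
                    if dwell_start is None:
                        dwell_start = ts[i]
                    if ts[i] - dwell_start >= config.dwell_time:
                        completed_at = float(ts[i])
                        dwell = (float(dwell_start), float(ts[i]))
                        start_idx = i
                        break
                else:
                    dwell_start = None  # dwell must be continuous
        if completed_at is None:
            if duration + 1e-9 < config.trial_limit:
                raise TACEvaluationError(
                    "trajectory ends before the trial limit with postures pending"
                )
            timed_out = True
        achieved.append(completed_at is not None)
        times.append(completed_at)
        dwells.append(dwell)
    trial_end = times[-1] if times[-1] is not None else float(min(ts[-1], limit_t))
    return TACTrialResult(
        posture_names=names,
        achieved=tuple(achieved),
        completion_times=tuple(times),
        dwell_intervals=tuple(dwells),
        trial_end=float(trial_end),
    )


def completion_rate_curve(
    result: TACTrialResult, config: TACConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous step function CR(t) = N_completed(t) / N_postures.

    Returns (breakpoints, values): CR(t) = values[j] for
    breakpoints[j] <= t < breakpoints[j+1]; breakpoints[0] = 0 with CR = 0.
    """
    done = sorted(t for t in result.completion_times if t is not None)
    n = config.n_postures
    breakpoints = np.concatenate([[0.0], np.asarray(done, dtype=float)])
    values = np.arange(len(done) + 1) / n
    return breakpoints, values


def completion_rate_at(
    t: float, breakpoints: np.ndarray, values: np.ndarray
) -> float:
    """Evaluate a completion-rate step curve at time t."""
    idx = np.searchsorted(breakpoints, t, side="right") - 1
    return float(values[max(idx, 0)])
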