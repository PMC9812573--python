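"""Real-time decoding loop over a replayable sample stream.

Each cycle grabs the LATEST 120 ms window from the source (samples arriving
while the previous cycle was processing are skipped, never queued — the
"latest window" lossy policy that keeps command latency bounded), runs the
three pipeline stages

    (1) raw sEMG -> normalized IEMG
    (2) CW-CNN regression
    (3) adaptive Kalman smoothing

and emits the smoothed 3-DOF angles plus a per-cycle computational-latency
record timed strictly around those three stages (source I/O and output
writing excluded, so the number is comparable across machines).

Replay uses a virtual clock advanced by a fixed number of samples per cycle,
so sessions are deterministic and machine-speed independent.  Skipped
samples still pass through the FIR filter (cheap) so the streaming filter
state always reflects the true contiguous signal history.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .kalman import AdaptTrace, KalmanConfig, KalmanState, kf_step, adapt_qr
from .model import CWCNNParams, forward
from .processing import (
    FIRSpec,
    FilterState,
    MVCProfile,
    N_CHANNELS,
    WINDOW_SAMPLES,
    normalize_iemg,
    rectify,
    fir_filter,
)

__all__ = [
    "EngineConfig",
    "LatencyRecord",
    "ReplaySource",
    "DecodingEngine",
    "SessionResult",
]


class StreamUnderrunError(RuntimeError):
    """Raised when fewer than one full window of samples is available."""


@dataclass(frozen=True)
class EngineConfig:
    """Real-time loop configuration."""

    window_ms: float = 120.0
    emg_rate: float = 500.0
    channels: int = N_CHANNELS
    #: virtual-clock samples consumed per cycle; 60 = contiguous windows,
    #: larger values emulate the lossy latest-window regime of a slow cycle
    advance_samples: int = WINDOW_SAMPLES
    kalman: KalmanConfig = field(default_factory=KalmanConfig)

    def __post_init__(self) -> None:
        n = self.window_ms * self.emg_rate / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"window_ms * emg_rate must give an integer sample count, got {n}"
            )
        if self.advance_samples < 1:
            raise ValueError("advance_samples must be >= 1")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.emg_rate / 1000.0))


@dataclass(frozen=True)
class LatencyRecord:
    """Computational latency of one cycle (stages 1-3 only)."""

    cycle: int
    start_clock: float
    end_clock: float

    @property
    def duration_ms(self) -> float:
        return (self.end_clock - self.start_clock) * 1000.0


class ReplaySource:
    """File/array-backed stream source with a virtual sample clock.

    Yields time-ordered (timestamp, row) samples; the engine reads the most
    recent window relative to its own cursor, mirroring a live ring buffer.
    """

    def __init__(self, timestamps: np.ndarray, samples: np.ndarray):
        ts = np.asarray(timestamps, dtype=float)
        s = np.asarray(samples, dtype=float)
        if ts.ndim != 1 or s.ndim != 2 or s.shape[0] != ts.size:
            raise ValueError("timestamps must be (N,), samples (N, C)")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        self.timestamps = ts
        self.samples = s

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def channels(self) -> int:
        return self.samples.shape[1]

    def window_ending_at(self, pos: int, length: int) -> tuple[np.ndarray, np.ndarray]:
        """Samples [pos-length, pos) and their timestamps."""
        if pos < length:
            raise StreamUnderrunError(
                f"need {length} samples, only {pos} available"
            )
        return self.timestamps[pos - length : pos], self.samples[pos - length : pos]


@dataclass
class SessionResult:
    """Everything a replayed session produced."""

    timestamps: np.ndarray          # (cycles,) window-end times, seconds
    raw_angles: np.ndarray          # (cycles, 3) CW-CNN output, degrees
    smoothed_angles: np.ndarray     # (cycles, 3) after Kalman, degrees
    latency: list[LatencyRecord]
    traces: list[AdaptTrace]        # one per DOF

    @property
    def cycles(self) -> int:
        return self.timestamps.size


class DecodingEngine:
    """Stateful signal -> model -> kalman pipeline over a stream source."""

    def __init__(
        self,
        params: CWCNNParams,
        profile: MVCProfile,
        fir: FIRSpec,
        config: EngineConfig | None = None,
    ):
        self.params = params
        self.profile = profile
        self.fir = fir
        self.config = config or EngineConfig()
        self.filter_state = FilterState.cold_start(fir, channels=self.config.channels)
        self.kalman_states: list[KalmanState] | None = None
        self.traces = [AdaptTrace.empty() for _ in range(3)]
        self._filtered_pos = 0  # samples already pushed through the FIR
        # rolling cache of the most recent window_samples filtered samples
        self._filtered_cache = np.zeros(
            (self.config.window_samples, self.config.channels)
        )

    def _advance_filter(self, source: ReplaySource, upto: int) -> None:
        """Rectify + FIR-filter all raw samples up to index ``upto``, keeping
        streaming state contiguous, and refresh the rolling window cache."""
        if upto <= self._filtered_pos:
            return
        raw = source.samples[self._filtered_pos : upto]
        filtered, self.filter_state = fir_filter(rectify(raw), self.fir, self.filter_state)
        self._filtered_pos = upto
        n = self.config.window_samples
        if filtered.shape[0] >= n:
            self._filtered_cache = filtered[-n:]
        else:
            self._filtered_cache = np.vstack(
                [self._filtered_cache[filtered.shape[0]:], filtered]
            )

    def run_cycle(
        self, source: ReplaySource, pos: int, cycle_index: int
    ) -> tuple[float, np.ndarray, np.ndarray, LatencyRecord]:
        """Process the window ending at sample index ``pos``.

        Returns (window_end_timestamp, raw 3-vector, smoothed 3-vector,
        latency record).
        """
        n = self.config.window_samples
        ts_win, _ = source.window_ending_at(pos, n)
        start = time.perf_counter()
        # stage 1: rectify + filter every new sample (keeps streaming state
        # contiguous even when the window skips ahead), then normalize the
        # most recent n filtered samples from the rolling cache
        self._advance_filter(source, pos)
        norm = normalize_iemg(self._filtered_cache, self.profile)
        # stage 2: CW-CNN regression
        raw_angles = forward(self.params, norm)
        # stage 3: adaptive Kalman smoothing, one scalar filter per DOF
        if self.kalman_states is None:
            self.kalman_states = [
                KalmanState.initial(raw_angles[d], self.config.kalman) for d in range(3)
            ]
        smoothed = np.empty(3)
        for d in range(3):
            state = self.kalman_states[d]
            P_prior = state.P
            gain = P_prior / (P_prior + state.R)
            innovation = raw_angles[d] - state.x
            state, smoothed[d] = kf_step(state, raw_angles[d])
            if self.config.kalman.adapt:
                state, q_hat, r_hat = adapt_qr(
                    state, innovation, gain, P_prior, self.config.kalman
                )
            else:
                q_hat, r_hat = state.Q, state.R
            self.traces[d].append(state.Q, state.R, q_hat, r_hat)
            self.kalman_states[d] = state
        end = time.perf_counter()
        record = LatencyRecord(cycle=cycle_index, start_clock=start, end_clock=end)
        return float(ts_win[-1]), raw_angles, smoothed, record

    def run_session(
        self, source: ReplaySource, duration_s: float | None = None
    ) -> SessionResult:
        """Replay the source until exhausted (or ``duration_s`` reached)."""
        n = self.config.window_samples
        if len(source) < n:
            raise StreamUnderrunError(
                f"session needs at least {n} samples, source has {len(source)}"
            )
        if source.channels != self.config.channels:
            raise ValueError("source channel count does not match engine config")
        times, raw_out, smooth_out, latency = [], [], [], []
        pos = n
        cycle = 0
        t0 = source.timestamps[0]
        while pos <= len(source):
            if duration_s is not None and source.timestamps[pos - 1] - t0 > duration_s:
                break
            t, raw_angles, smoothed, rec = self.run_cycle(source, pos, cycle)
            times.append(t)
            raw_out.append(raw_angles)
            smooth_out.append(smoothed)
            latency.append(rec)
            pos += self.config.advance_samples
            cycle += 1
        return SessionResult(
            timestamps=np.asarray(times),
            raw_angles=np.asarray(raw_out).reshape(-1, 3),
            smoothed_angles=np.asarray(smooth_out).reshape(-1, 3),
            latency=latency,
            traces=self.traces,
        )
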