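"""Raw sEMG to normalized IEMG: rectify, low-pass FIR filter, MVC min-max
normalization, on 120 ms sliding windows with streaming filter state.

The pipeline per channel i is

    IEMG_i      = filter(abs(EMG_i))
    IMVC_i      = filter(abs(MVC_i))
    IEMGnorm_i  = (IEMG_i - min(IMVC_i)) / (max(IMVC_i) - min(IMVC_i))

with the normalized output clipped to [0, 1] (live activations can exceed
the recorded maximum voluntary contraction).  Filtering is causal and
streamable: processing a long recording window by window with carried state
is bit-identical to filtering the concatenated stream in one shot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import firwin

from .synth import N_CHANNELS, RawEMGStream

__all__ = [
    "WINDOW_SAMPLES",
    "FIRSpec",
    "FilterState",
    "MVCProfile",
    "RawEMGWindow",
    "NormalizedIEMGWindow",
    "default_fir",
    "rectify",
    "fir_filter",
    "compute_mvc_profile",
    "normalize_iemg",
    "process_window",
]

#: 120 ms window at 500 Hz
WINDOW_SAMPLES = 60


class MVCProfileError(ValueError):
    """Raised when an MVC recording yields a degenerate (flat) channel."""


@dataclass(frozen=True)
class FIRSpec:
    """A causal FIR low-pass filter given by its tap coefficients."""

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 1 or c.size == 0 or not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be a nonempty finite 1-D sequence")
        object.__setattr__(self, "coefficients", c)

    @property
    def dc_gain(self) -> float:
        return float(self.coefficients.sum())

    @property
    def order(self) -> int:
        return self.coefficients.size - 1


def default_fir(cutoff_hz: float = 3.0, fs: float = 500.0, numtaps: int = 101) -> FIRSpec:
    """Linear-phase windowed-sinc low-pass with unit DC gain.

    The envelope extractor for IEMG: a 3 Hz cutoff at 500 Hz retains the
    slow amplitude modulation of muscle activity while suppressing the
    carrier.  Taps are a design default and can be replaced via config.
    """
    return FIRSpec(coefficients=firwin(numtaps, cutoff_hz, fs=fs))


@dataclass
class FilterState:
    """Per-channel delay line for streaming FIR filtering.

    Holds the last ``order`` raw input samples per channel; a fresh (cold
    start) state is all zeros, equivalent to the stream being preceded by
    silence.
    """

    history: np.ndarray  # (order, channels): most recent inputs, oldest first

    @classmethod
    def cold_start(cls, spec: FIRSpec, channels: int = N_CHANNELS) -> "FilterState":
        return cls(history=np.zeros((spec.order, channels)))

    @property
    def channels(self) -> int:
        return self.history.shape[1]


def rectify(samples: np.ndarray) -> np.ndarray:
    """Full-wave rectification: elementwise absolute value (idempotent)."""
    return np.abs(np.asarray(samples, dtype=float))


def fir_filter(
    samples: np.ndarray, spec: FIRSpec, state: FilterState
) -> tuple[np.ndarray, FilterState]:
    """Causal per-channel FIR convolution with carried streaming state.

    Returns the filtered block and the updated state; chaining consecutive
    blocks reproduces one-shot filtering of the concatenation bit-exactly.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[1] != state.channels:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, state has {state.channels}"
        )
    order = spec.order
    padded = np.vstack([state.history, x])  # (order + n, channels)
    if x.shape[0] == 0:
        return x.copy(), state
    # y[i, c] = sum_k b[k] * padded[order + i - k, c]: realized as a dot of
    # the reversed taps with each length-(order+1) sliding window, so the
    # per-sample arithmetic is identical whether the stream is processed in
    # one shot or in chunks with carried state
    windows = sliding_window_view(padded, order + 1, axis=0)  # (n, ch, taps)
    y = windows @ spec.coefficients[::-1]
    new_history = padded[-order:] if order else np.empty((0, x.shape[1]))
    return y, FilterState(history=new_history.copy())


@dataclass(frozen=True)
class MVCProfile:
    """Per-channel min/max of the integrated MVC signal (IEMG units)."""

    min: np.ndarray  # (32,)
    max: np.ndarray  # (32,)

    def __post_init__(self) -> None:
        lo = np.asarray(self.min, dtype=float)
        hi = np.asarray(self.max, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("min and max must be equal-length 1-D arrays")
        bad = np.nonzero(~(hi > lo))[0]
        if bad.size:
            raise MVCProfileError(
                f"degenerate MVC channels (max <= min): {bad.tolist()}"
            )
        object.__setattr__(self, "min", lo)
        object.__setattr__(self, "max", hi)

    @property
    def channels(self) -> int:
        return self.min.size

    @property
    def span(self) -> np.ndarray:
        return self.max - self.min


def compute_mvc_profile(mvc_stream: RawEMGStream, spec: FIRSpec) -> MVCProfile:
    """Rectify + filter the MVC recording and take per-channel min/max.

    The first ``order`` output samples are the cold-start transient and are
    excluded, so the profile reflects the settled envelope only.
    """
    samples = mvc_stream.samples
    if samples.shape[0] <= spec.order:
        raise ValueError(
            f"MVC recording too short: need > {spec.order} samples for the "
            f"filter to settle, got {samples.shape[0]}"
        )
    state = FilterState.cold_start(spec, channels=samples.shape[1])
    imvc, _ = fir_filter(rectify(samples), spec, state)
    settled = imvc[spec.order:]
    return MVCProfile(min=settled.min(axis=0), max=settled.max(axis=0))


@dataclass(frozen=True)
class RawEMGWindow:
    """One 120 ms acquisition: 60 samples x 32 channels at 500 Hz."""

    samples: np.ndarray
    start_timestamp: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.shape != (WINDOW_SAMPLES, N_CHANNELS):
            raise ValueError(
                f"window must be ({WINDOW_SAMPLES}, {N_CHANNELS}), got {s.shape}"
            )
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class NormalizedIEMGWindow:
    """MVC-normalized IEMG window; all values in [0, 1] after clipping."""

    values: np.ndarray
    start_timestamp: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (WINDOW_SAMPLES, N_CHANNELS):
            raise ValueError(
                f"window must be ({WINDOW_SAMPLES}, {N_CHANNELS}), got {v.shape}"
            )
        object.__setattr__(self, "values", v)


def normalize_iemg(iemg: np.ndarray, profile: MVCProfile) -> np.ndarray:
    """Min-max normalize IEMG against the MVC profile, clipped to [0, 1]."""
    x = np.asarray(iemg, dtype=float)
    return np.clip((x - profile.min) / profile.span, 0.0, 1.0)


def process_window(
    raw: RawEMGWindow, profile: MVCProfile, spec: FIRSpec, state: FilterState
) -> tuple[NormalizedIEMGWindow, FilterState]:
    """rectify -> fir_filter -> normalize_iemg on one 60 x 32 window."""
    filtered, new_state = fir_filter(rectify(raw.samples), spec, state)
    return (
        NormalizedIEMGWindow(
            values=normalize_iemg(filtered, profile),
            start_timestamp=raw.start_timestamp,
        ),
        new_state,
    )
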