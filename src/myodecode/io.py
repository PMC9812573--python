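"""Timestamped delimited-text I/O for streams, profiles, and scripts.

All on-disk stream formats are TSV with a header row: column 1 is the
timestamp in seconds, followed by 32 EMG channel columns (``ch01``..``ch32``)
or 3 angle columns (``dof1``..``dof3``).  MVC profiles are 32-row TSVs
(channel, min, max).  Motion scripts are plain text, one ``<motion_id>
<duration_s>`` pair per line (``#`` comments allowed).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kalman import AdaptTrace
from .processing import MVCProfile
from .synth import AngleStream, MotionScript, RawEMGStream, N_CHANNELS

__all__ = [
    "write_emg_tsv",
    "read_emg_tsv",
    "write_angles_tsv",
    "read_angles_tsv",
    "write_mvc_profile",
    "read_mvc_profile",
    "read_motion_script",
    "write_motion_script",
    "write_latency_tsv",
    "write_trace_tsv",
]

_EMG_COLS = [f"ch{i + 1:02d}" for i in range(N_CHANNELS)]
_DOF_COLS = ["dof1", "dof2", "dof3"]


def write_emg_tsv(stream: RawEMGStream, path) -> None:
    df = pd.DataFrame(stream.samples, columns=_EMG_COLS)
    df.insert(0, "timestamp", stream.timestamps)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_emg_tsv(path, rate: float = 500.0) -> RawEMGStream:
    df = pd.read_csv(path, sep="\t")
    return RawEMGStream(
        timestamps=df["timestamp"].to_numpy(),
        samples=df[_EMG_COLS].to_numpy(),
        rate=rate,
    )


def write_angles_tsv(timestamps: np.ndarray, angles: np.ndarray, path) -> None:
    df = pd.DataFrame(np.asarray(angles), columns=_DOF_COLS)
    df.insert(0, "timestamp", np.asarray(timestamps))
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_angles_tsv(path, rate: float = 120.0) -> AngleStream:
    df = pd.read_csv(path, sep="\t")
    return AngleStream(
        timestamps=df["timestamp"].to_numpy(),
        angles=df[_DOF_COLS].to_numpy(),
        rate=rate,
    )


def read_angles_tsv_raw(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an angle TSV without ground-truth invariants (decoded streams)."""
    df = pd.read_csv(path, sep="\t")
    return df["timestamp"].to_numpy(), df[_DOF_COLS].to_numpy()


def write_mvc_profile(profile: MVCProfile, path) -> None:
    df = pd.DataFrame(
        {
            "channel": np.arange(1, profile.channels + 1),
            "min": profile.min,
            "max": profile.max,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_mvc_profile(path) -> MVCProfile:
    df = pd.read_csv(path, sep="\t")
    return MVCProfile(min=df["min"].to_numpy(), max=df["max"].to_numpy())


def read_motion_script(path) -> MotionScript:
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        motion, duration = line.split()
        pairs.append((motion, float(duration)))
    return MotionScript.from_pairs(pairs)


def write_motion_script(script: MotionScript, path) -> None:
    Path(path).write_text(
        "".join(f"{m}\t{d:g}\n" for m, d in script.entries)
    )


def write_latency_tsv(records, path) -> None:
    df = pd.DataFrame(
        {
            "cycle": [r.cycle for r in records],
            "duration_ms": [r.duration_ms for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_trace_tsv(trace: AdaptTrace, path) -> None:
    arrays = trace.as_arrays()
    df = pd.DataFrame(
        {
            "k": np.arange(1, len(trace.Q) + 1),
            "Q": arrays["Q"],
            "R": arrays["R"],
            "Qhat": arrays["Qhat"],
            "Rhat": arrays["Rhat"],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
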