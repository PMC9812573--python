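"""Channel-wise CNN (CW-CNN) regression from normalized IEMG to joint angles.

Architecture: six temporal filters of length 60 are applied channel-wise to a
[60 x 32] normalized-IEMG window, each compressing the time dimension to one
value per channel.  The resulting six [1 x 32] feature maps ("force
patterns") are flattened row-major (filter-major) into a [1 x 192] vector and
mapped by a single fully connected layer to the three joint angles (degrees).

Training is mean-squared-error regression with the Adam optimizer; the model
is small enough (6*60 + 6 conv parameters, 3*192 + 3 fc parameters) that
gradients are computed in closed form with numpy.  Transfer to a new session
freezes the convolutional layer bit-exactly and retrains only the fully
connected layer ("layer transfer").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .processing import N_CHANNELS, WINDOW_SAMPLES
from .synth import AngleStream

__all__ = [
    "N_FILTERS",
    "N_FEATURES",
    "CWCNNParams",
    "TrainingConfig",
    "CVReport",
    "forward",
    "forward_batch",
    "pair_and_resample",
    "train_initial",
    "layer_transfer",
    "save_params",
    "load_params",
]

N_FILTERS = 6
N_FEATURES = N_FILTERS * N_CHANNELS  # 192
N_DOF = 3


class PairingError(ValueError):
    """Raised when EMG and angle streams cannot be paired in time."""


class TrainingError(RuntimeError):
    """Raised on non-finite loss or insufficient data."""


@dataclass(frozen=True)
class CWCNNParams:
    """All weights of the two-layer CW-CNN."""

    conv_w: np.ndarray  # (6, 60) temporal filters
    conv_b: np.ndarray  # (6,) one bias per filter
    fc_w: np.ndarray    # (3, 192)
    fc_b: np.ndarray    # (3,) degrees
    activation: str = "relu"  # post-conv nonlinearity: "relu" or "identity"

    def __post_init__(self) -> None:
        shapes = {
            "conv_w": (np.asarray(self.conv_w, float), (N_FILTERS, WINDOW_SAMPLES)),
            "conv_b": (np.asarray(self.conv_b, float), (N_FILTERS,)),
            "fc_w": (np.asarray(self.fc_w, float), (N_DOF, N_FEATURES)),
            "fc_b": (np.asarray(self.fc_b, float), (N_DOF,)),
        }
        for name, (arr, want) in shapes.items():
            if arr.shape != want:
                raise ValueError(f"{name} must have shape {want}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @classmethod
    def init_random(cls, seed: int, activation: str = "relu") -> "CWCNNParams":
        rng = np.random.default_rng(seed)
        return cls(
            conv_w=rng.standard_normal((N_FILTERS, WINDOW_SAMPLES)) / np.sqrt(WINDOW_SAMPLES),
            conv_b=np.zeros(N_FILTERS),
            fc_w=rng.standard_normal((N_DOF, N_FEATURES)) / np.sqrt(N_FEATURES),
            fc_b=np.zeros(N_DOF),
            activation=activation,
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for (re)training the CW-CNN."""

    loss: str = "mse"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 100
    folds: int = 10
    seed: int = 0
    batch_size: int = 64
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mse" or self.optimizer != "adam":
            raise ValueError("only mse loss with adam optimizer is implemented")


@dataclass(frozen=True)
class CVReport:
    """Cross-validation record: per-fold, per-DOF validation Pearson CC."""

    fold_cc: np.ndarray   # (folds, 3)
    final_loss: float

    @property
    def folds(self) -> int:
        return self.fold_cc.shape[0]

    @property
    def mean_cc(self) -> np.ndarray:
        return self.fold_cc.mean(axis=0)


def _activate(z: np.ndarray, tag: str) -> np.ndarray:
    return np.maximum(z, 0.0) if tag == "relu" else z


def forward_batch(params: CWCNNParams, windows: np.ndarray) -> np.ndarray:
    """Forward pass on (B, 60, 32) windows -> (B, 3) angles in degrees."""
    x = np.asarray(windows, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (WINDOW_SAMPLES, N_CHANNELS):
        raise ValueError(
            f"windows must be (B, {WINDOW_SAMPLES}, {N_CHANNELS}), got {x.shape}"
        )
    # force pattern: one value per (filter, channel)
    z = np.einsum("jt,btc->bjc", params.conv_w, x) + params.conv_b[None, :, None]
    feats = _activate(z, params.activation).reshape(x.shape[0], N_FEATURES)
    return feats @ params.fc_w.T + params.fc_b


def forward(params: CWCNNParams, window: np.ndarray) -> np.ndarray:
    """Forward pass on one (60, 32) window -> 3-vector of angles (degrees)."""
    w = np.asarray(window, dtype=float)
    if w.shape != (WINDOW_SAMPLES, N_CHANNELS):
        raise ValueError(
            f"window must be ({WINDOW_SAMPLES}, {N_CHANNELS}), got {w.shape}"
        )
    return forward_batch(params, w[None])[0]


def pair_and_resample(
    emg_timestamps: np.ndarray,
    emg_values: np.ndarray,
    angle_stream: AngleStream,
    window_len: int = WINDOW_SAMPLES,
    stride: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Build supervised (window, angle) pairs from asynchronous streams.

    The angle stream (120 Hz) is up-sampled onto the EMG timestamps (500 Hz)
    by linear interpolation; each pair is one ``window_len``-sample block of
    the EMG-rate values labeled with the up-sampled angle at the window's
    LAST sample (causal labeling, matching real-time use).

    Returns (windows (N, window_len, C), targets (N, 3)).
    """
    ts = np.asarray(emg_timestamps, dtype=float)
    vals = np.asarray(emg_values, dtype=float)
    if ts.size != vals.shape[0]:
        raise ValueError("timestamps and values disagree in length")
    a_ts, a_val = angle_stream.timestamps, angle_stream.angles
    if ts[-1] < a_ts[0] or ts[0] > a_ts[-1]:
        raise PairingError("EMG and angle streams do not overlap in time")
    upsampled = np.column_stack(
        [np.interp(ts, a_ts, a_val[:, d]) for d in range(N_DOF)]
    )
    m = ts.size
    if m < window_len:
        raise PairingError(f"need at least {window_len} EMG samples, got {m}")
    n_pairs = (m - window_len) // stride + 1
    idx = np.arange(n_pairs) * stride
    windows = np.stack([vals[i : i + window_len] for i in idx])
    targets = upsampled[idx + window_len - 1]
    return windows, targets


def _mse_grads(
    params: CWCNNParams, x: np.ndarray, y: np.ndarray, train_conv: bool
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and analytic gradients on one batch."""
    b = x.shape[0]
    z = np.einsum("jt,btc->bjc", params.conv_w, x) + params.conv_b[None, :, None]
    a = _activate(z, params.activation)
    feats = a.reshape(b, N_FEATURES)
    pred = feats @ params.fc_w.T + params.fc_b
    err = pred - y
    loss = float(np.mean(err**2))
    d_pred = 2.0 * err / err.size
    grads = {
        "fc_w": d_pred.T @ feats,
        "fc_b": d_pred.sum(axis=0),
    }
    if train_conv:
        d_feats = d_pred @ params.fc_w
        d_a = d_feats.reshape(b, N_FILTERS, N_CHANNELS)
        d_z = d_a * (z > 0) if params.activation == "relu" else d_a
        grads["conv_w"] = np.einsum("bjc,btc->jt", d_z, x)
        grads["conv_b"] = d_z.sum(axis=(0, 2))
    return loss, grads


def _fit(
    params: CWCNNParams,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
    train_conv: bool,
    rng: np.random.Generator,
) -> tuple[CWCNNParams, float]:
    """Adam/MSE minibatch training loop; returns (params, final epoch loss)."""
    names = ["fc_w", "fc_b"] + (["conv_w", "conv_b"] if train_conv else [])
    weights = {n: getattr(params, n).copy() for n in names}
    m = {n: np.zeros_like(w) for n, w in weights.items()}
    v = {n: np.zeros_like(w) for n, w in weights.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = x.shape[0]
    last_loss = np.nan
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            batch = order[lo : lo + config.batch_size]
            cur = replace(params, **weights)
            loss, grads = _mse_grads(cur, x[batch], y[batch], train_conv)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at step {step}")
            epoch_loss += loss * batch.size
            step += 1
            for nme in names:
                g = grads[nme]
                m[nme] = beta1 * m[nme] + (1 - beta1) * g
                v[nme] = beta2 * v[nme] + (1 - beta2) * g**2
                mhat = m[nme] / (1 - beta1**step)
                vhat = v[nme] / (1 - beta2**step)
                weights[nme] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        last_loss = epoch_loss / n
    return replace(params, **weights), last_loss


def _per_dof_cc(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    out = np.empty(N_DOF)
    for d in range(N_DOF):
        p, t = pred[:, d], truth[:, d]
        if p.std() == 0 or t.std() == 0:
            out[d] = np.nan
        else:
            out[d] = np.mean((p - p.mean()) * (t - t.mean())) / (p.std() * t.std())
    return out


def _fold_slices(n: int, folds: int, groups: np.ndarray | None) -> list[np.ndarray]:
    """Validation index sets: grouped by trial id when given, else contiguous
    blocks (avoids temporal leakage between neighbouring windows)."""
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if uniq.size < 2:
            raise TrainingError("need at least 2 distinct groups for grouped CV")
        chunks = np.array_split(uniq, folds)
        return [np.nonzero(np.isin(groups, ch))[0] for ch in chunks if ch.size]
    return [s for s in np.array_split(np.arange(n), folds) if s.size]


def _cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
    base: CWCNNParams,
    train_conv: bool,
    groups: np.ndarray | None,
) -> np.ndarray:
    fold_cc = []
    for i, val_idx in enumerate(_fold_slices(x.shape[0], config.folds, groups)):
        train_mask = np.ones(x.shape[0], dtype=bool)
        train_mask[val_idx] = False
        rng = np.random.default_rng(config.seed + 1000 + i)
        fitted, _ = _fit(base, x[train_mask], y[train_mask], config, train_conv, rng)
        pred = forward_batch(fitted, x[val_idx])
        fold_cc.append(_per_dof_cc(pred, y[val_idx]))
    return np.asarray(fold_cc)


def train_initial(
    windows: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig | None = None,
    groups: np.ndarray | None = None,
) -> tuple[CWCNNParams, CVReport]:
    """Initial training with k-fold cross-validation (default 10-fold).

    Folds are grouped by trial when ``groups`` is given, else split as
    contiguous blocks.  The returned params are refit on ALL data; the report
    carries the per-fold, per-DOF validation CC.  Deterministic given seed.
    """
    config = config or TrainingConfig()
    x = np.asarray(windows, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.shape[0] < config.folds * 2:
        raise TrainingError(
            f"need >= {config.folds * 2} pairs for {config.folds}-fold CV, got {x.shape[0]}"
        )
    base = CWCNNParams.init_random(config.seed, activation=config.activation)
    fold_cc = _cross_validate(x, y, config, base, train_conv=True, groups=groups)
    rng = np.random.default_rng(config.seed)
    final, loss = _fit(base, x, y, config, train_conv=True, rng=rng)
    return final, CVReport(fold_cc=fold_cc, final_loss=loss)


def layer_transfer(
    params: CWCNNParams,
    windows: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig | None = None,
    groups: np.ndarray | None = None,
) -> tuple[CWCNNParams, CVReport]:
    """Adapt a trained model to a new session by layer transfer.

    The convolutional layer (filters and biases) is frozen bit-exactly; only
    the fully connected layer is retrained on the new data (default 5-fold
    CV on the smaller new-session dataset).
    """
    config = config or TrainingConfig(folds=5)
    x = np.asarray(windows, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.shape[0] == 0:
        raise TrainingError("new dataset is empty")
    if x.shape[0] < config.folds * 2:
        raise TrainingError(
            f"need >= {config.folds * 2} pairs for {config.folds}-fold CV, got {x.shape[0]}"
        )
    fold_cc = _cross_validate(x, y, config, params, train_conv=False, groups=groups)
    rng = np.random.default_rng(config.seed)
    final, loss = _fit(params, x, y, config, train_conv=False, rng=rng)
    assert final.conv_w is params.conv_w or np.array_equal(final.conv_w, params.conv_w)
    return final, CVReport(fold_cc=fold_cc, final_loss=loss)


_FORMAT_VERSION = 1


def save_params(params: CWCNNParams, path) -> None:
    """Persist all weight arrays plus metadata; round-trips bit-exactly."""
    np.savez(
        path,
        format_version=_FORMAT_VERSION,
        conv_w=params.conv_w,
        conv_b=params.conv_b,
        fc_w=params.fc_w,
        fc_b=params.fc_b,
        activation=np.asarray(params.activation),
    )


def load_params(path) -> CWCNNParams:
    with np.load(path, allow_pickle=False) as f:
        version = int(f["format_version"])
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        return CWCNNParams(
            conv_w=f["conv_w"],
            conv_b=f["conv_b"],
            fc_w=f["fc_w"],
            fc_b=f["fc_b"],
            activation=str(f["activation"]),
        )
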