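"""Per-DOF scalar adaptive Kalman smoothing of decoded joint angles.

The decoded angle stream oscillates (low effective output rate plus
regression noise), which would damage prosthesis motors if used directly as
a command signal.  Each DOF is smoothed independently by a scalar Kalman
filter with a random-walk state model:

    K(k) = P(k-1) / (P(k-1) + R)
    x(k) = x(k-1) + K(k) * (z(k) - x(k-1))
    P(k) = (1 - K(k)) * P(k-1) + Q

The process covariance Q and observation covariance R adapt online.  After
each step, instantaneous variance estimates Qhat/Rhat are folded into Q and R
as running means:

    Q(k+1) = Q(k) + (Qhat(k+1) - Q(k)) / (k+1)
    R(k+1) = R(k) + (Rhat(k+1) - R(k)) / (k+1)

The instantaneous estimates use innovation-based (Mehra-style) moment
matching on the innovation d = z(k) - x(k-1):

    Rhat = max(d^2 - P(k-1), r_floor)       # innovation variance is P + R
    Qhat = max(K(k)^2 * d^2, q_floor)       # variance injected by the update

Floors keep both covariances strictly positive.  All covariances are in
squared degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KalmanConfig",
    "KalmanState",
    "AdaptTrace",
    "kf_step",
    "adapt_qr",
    "smooth_stream",
    "steady_state_P",
]

Q_INIT_DEFAULT = 0.05
R_INIT_DEFAULT = 0.4
Q_FLOOR_DEFAULT = 1e-6
R_FLOOR_DEFAULT = 1e-4


@dataclass(frozen=True)
class KalmanConfig:
    """Tunables of the adaptive smoother (covariances in deg^2)."""

    q_init: float = Q_INIT_DEFAULT
    r_init: float = R_INIT_DEFAULT
    q_floor: float = Q_FLOOR_DEFAULT
    r_floor: float = R_FLOOR_DEFAULT
    adapt: bool = True

    def __post_init__(self) -> None:
        if not (self.q_init > 0 and self.r_init > 0):
            raise ValueError("q_init and r_init must be positive")
        if not (self.q_floor > 0 and self.r_floor > 0):
            raise ValueError("floors must be positive")


@dataclass(frozen=True)
class KalmanState:
    """Scalar filter state for one DOF."""

    x: float   # filtered angle, degrees
    P: float   # error covariance, deg^2
    Q: float   # transition covariance, deg^2
    R: float   # observation covariance, deg^2
    k: int = 0 # iteration count

    def __post_init__(self) -> None:
        if not (self.P > 0 and self.Q > 0 and self.R > 0):
            raise ValueError("P, Q, R must remain positive")
        if self.k < 0:
            raise ValueError("iteration count must be nonnegative")

    @classmethod
    def initial(cls, first_observation: float, config: KalmanConfig) -> "KalmanState":
        # x starts at the first observation and P at R: avoids a startup
        # transient toward zero.
        return cls(
            x=float(first_observation),
            P=config.r_init,
            Q=config.q_init,
            R=config.r_init,
            k=0,
        )


@dataclass
class AdaptTrace:
    """Per-iteration record of the covariance adaptation (one DOF)."""

    Q: list[float]
    R: list[float]
    Qhat: list[float]
    Rhat: list[float]

    @classmethod
    def empty(cls) -> "AdaptTrace":
        return cls(Q=[], R=[], Qhat=[], Rhat=[])

    def append(self, Q: float, R: float, Qhat: float, Rhat: float) -> None:
        self.Q.append(Q)
        self.R.append(R)
        self.Qhat.append(Qhat)
        self.Rhat.append(Rhat)

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v) for k, v in vars(self).items()}


def kf_step(state: KalmanState, z: float) -> tuple[KalmanState, float]:
    """One Kalman iteration; returns (updated state, filtered value).

    The gain K = P/(P+R) lies strictly in (0, 1) whenever P, R > 0, so the
    filtered value is always a proper convex combination of prior and
    observation.
    """
    if not np.isfinite(z):
        raise ValueError(f"observation must be finite, got {z}")
    K = state.P / (state.P + state.R)
    x_new = state.x + K * (z - state.x)
    P_new = (1.0 - K) * state.P + state.Q
    return replace(state, x=x_new, P=P_new, k=state.k + 1), x_new


def adapt_qr(
    state: KalmanState,
    innovation: float,
    gain: float,
    P_prior: float,
    config: KalmanConfig,
) -> tuple[KalmanState, float, float]:
    """Update Q and R from the current innovation (running-mean recursion).

    ``P_prior`` and ``gain`` are the pre-update covariance P(k-1) and the
    gain K(k) of the step just taken; ``state.k`` must already count that
    step.  Returns (state with new Q/R, Qhat, Rhat).
    """
    q_hat = max(gain**2 * innovation**2, config.q_floor)
    r_hat = max(innovation**2 - P_prior, config.r_floor)
    k = state.k  # iterations completed so far
    q_new = state.Q + (q_hat - state.Q) / (k + 1)
    r_new = state.R + (r_hat - state.R) / (k + 1)
    return (
        replace(state, Q=max(q_new, config.q_floor), R=max(r_new, config.r_floor)),
        q_hat,
        r_hat,
    )


def smooth_stream(
    observations: np.ndarray,
    config: KalmanConfig | None = None,
) -> tuple[np.ndarray, list[AdaptTrace]]:
    """Smooth an (N,) or (N, D) observation series, one filter per column.

    Returns the smoothed series (same shape) and one AdaptTrace per DOF.
    An empty series yields an empty output and empty traces.
    """
    config = config or KalmanConfig()
    z = np.asarray(observations, dtype=float)
    squeeze = z.ndim == 1
    if squeeze:
        z = z[:, None]
    n, d = z.shape
    out = np.empty_like(z)
    traces = [AdaptTrace.empty() for _ in range(d)]
    if n == 0:
        return (out[:, 0] if squeeze else out), traces
    for j in range(d):
        state = KalmanState.initial(z[0, j], config)
        for i in range(n):
            P_prior = state.P
            gain = P_prior / (P_prior + state.R)
            innovation = z[i, j] - state.x
            state, out[i, j] = kf_step(state, z[i, j])
            if config.adapt:
                state, q_hat, r_hat = adapt_qr(
                    state, innovation, gain, P_prior, config
                )
            else:
                q_hat, r_hat = state.Q, state.R
            traces[j].append(state.Q, state.R, q_hat, r_hat)
    return (out[:, 0] if squeeze else out), traces


def steady_state_P(Q: float, R: float) -> float:
    """Fixed point of the covariance recursion with adaptation off.

    P' = P*R/(P+R) + Q has fixed point P^2 - Q*P - Q*R = 0, i.e.
    P* = (Q + sqrt(Q^2 + 4*Q*R)) / 2.
    """
    return 0.5 * (Q + np.sqrt(Q**2 + 4.0 * Q * R))
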