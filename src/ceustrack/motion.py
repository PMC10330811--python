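"""Constant-velocity Kalman filter and the Gaussian temporal motion attention.

The lesion's breathing-driven motion is modeled as a linear-Gaussian
system with state ``x = [u_x, u_y, v_x, v_y]`` (position, velocity in
pixels and pixels/frame):

    x_t = A x_{t-1} + w,      w ~ N(0, Q)
    z_t = H x_t + s,          s ~ N(0, R)

with A the constant-velocity transition (dt = 1 frame) and H observing
position only.  Optical flow supplies the position measurement
``z = previous center + u_dot``.  The filter runs the standard
predict/update recursion:

    P-  = A P A^T + Q
    K   = P- H^T (H P- H^T + R)^{-1}
    x^  = x- + K (z - H x-)
    P^  = (I - K H) P-

The filtered position becomes the center l_c of a Gaussian spatial prior
over candidate locations l_i:

    Att(l_i) = exp(-d_i^2 / (2 sigma^2)),   d_i = ||l_i - l_c||_2

where sigma is the standard deviation of the per-frame moving distance
over the last 10 frames, clamped to [3, 9] px (too small makes the prior
over-conservative, too large makes it uninformative).  Candidates with
Att below 1e-4 are deemed invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotionState",
    "KalmanParams",
    "AttentionMap",
    "kf_predict",
    "kf_update",
    "flow_to_measurement",
    "sigma_from_history",
    "attention_map",
]

SIGMA_MIN = 3.0
SIGMA_MAX = 9.0
SIGMA_DEFAULT = 6.0  # used before enough motion history exists
ATTENTION_THRESHOLD = 1e-4
HISTORY_LENGTH = 10


def _white_accel_q(q: float) -> np.ndarray:
    """Discrete white-acceleration covariance (dt = 1) for [x, y, vx, vy]."""
    Q = np.zeros((4, 4))
    for pos, vel in ((0, 2), (1, 3)):
        Q[pos, pos] = q / 4.0
        Q[pos, vel] = Q[vel, pos] = q / 2.0
        Q[vel, vel] = q
    return Q


def _check_psd(P: np.ndarray, name: str = "P") -> None:
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(0.5 * (P + P.T))
    if eigvals.min() < -1e-8:
        raise ValueError(f"{name} must be positive semidefinite (min eig {eigvals.min():.3g})")


@dataclass
class MotionState:
    """Kalman state: position+velocity mean ``x`` (4,) and covariance ``P`` (4,4)."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(4)
        self.P = np.asarray(self.P, dtype=float).reshape(4, 4)
        _check_psd(self.P)

    @property
    def position(self) -> np.ndarray:
        return self.x[:2]

    @property
    def velocity(self) -> np.ndarray:
        return self.x[2:]

    @classmethod
    def initial(cls, center: tuple[float, float] | np.ndarray) -> "MotionState":
        """Known start position, zero velocity, uncertain velocity prior."""
        x = np.array([center[0], center[1], 0.0, 0.0])
        P = np.diag([1.0, 1.0, 10.0, 10.0])
        return cls(x, P)


@dataclass
class KalmanParams:
    """Constant-velocity system matrices (dt = 1 frame)."""

    A: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [1.0, 0.0, 1.0, 0.0],
                [0.0, 1.0, 0.0, 1.0],
                [0.0, 0.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
    )
    H: np.ndarray = field(
        default_factory=lambda: np.array(
            [[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]]
        )
    )
    Q: np.ndarray = field(default_factory=lambda: _white_accel_q(0.25))
    R: np.ndarray = field(default_factory=lambda: 4.0 * np.eye(2))

    @classmethod
    def default(cls, q: float = 0.25, r: float = 4.0) -> "KalmanParams":
        """White-acceleration process noise with acceleration variance ``q``
        (px^2/frame^4) — breathing is smooth but not constant-velocity, and
        this lets position uncertainty grow realistically through stretches
        without measurements (shadow frames)."""
        return cls(Q=_white_accel_q(q), R=r * np.eye(2))


def kf_predict(state: MotionState, params: KalmanParams) -> MotionState:
    """Time update: ``x- = A x``, ``P- = A P A^T + Q``."""
    A = params.A
    x_pred = A @ state.x
    P_pred = A @ state.P @ A.T + params.Q
    P_pred = 0.5 * (P_pred + P_pred.T)
    return MotionState(x_pred, P_pred)


def kf_update(
    state_pred: MotionState,
    z: np.ndarray | tuple[float, float],
    params: KalmanParams,
    R: np.ndarray | None = None,
) -> MotionState:
    """Measurement update with the Kalman gain.

    ``R`` overrides ``params.R`` (the tracker trusts a matched template
    center more than a raw optical-flow measurement).
    """
    z = np.asarray(z, dtype=float).reshape(-1)
    if not np.all(np.isfinite(z)):
        raise ValueError(f"measurement must be finite, got {z}")
    H = params.H
    Rm = params.R if R is None else np.asarray(R, dtype=float)
    S = H @ state_pred.P @ H.T + Rm
    try:
        K = np.linalg.solve(S.T, (state_pred.P @ H.T).T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular innovation covariance S={S!r} in Kalman update"
        ) from exc
    x_new = state_pred.x + K @ (z - H @ state_pred.x)
    P_new = (np.eye(state_pred.P.shape[0]) - K @ H) @ state_pred.P
    P_new = 0.5 * (P_new + P_new.T)
    # clip tiny negative eigenvalues from round-off
    eigvals, eigvecs = np.linalg.eigh(P_new)
    if eigvals.min() < 0:
        P_new = (eigvecs * np.clip(eigvals, 0.0, None)) @ eigvecs.T
    return MotionState(x_new, P_new)


def flow_to_measurement(
    prev_center: np.ndarray | tuple[float, float],
    flow,
) -> np.ndarray | None:
    """Turn an aggregated ROI flow into a position measurement.

    ``z = prev_center + u_dot`` (dt = 1 frame); a degenerate or unreliable
    flow yields ``None`` — the filter then does a predict-only step.
    """
    if flow is None or getattr(flow, "degenerate", False) or getattr(flow, "unreliable", False):
        return None
    prev = np.asarray(prev_center, dtype=float)
    return prev + flow.vector


def sigma_from_history(recent_displacements) -> float:
    """Sample sd of the last <=10 per-frame moving distances; with fewer than
    two samples returns the mid-range default (6 px)."""
    d = np.asarray(list(recent_displacements)[-HISTORY_LENGTH:], dtype=float)
    if d.size < 2:
        return SIGMA_DEFAULT
    return float(np.std(d, ddof=1))


@dataclass
class AttentionMap:
    """Gaussian motion prior evaluated on a grid of candidate centers."""

    values: np.ndarray  # Att in [0, 1]
    center: np.ndarray  # l_c, (x, y) image coords
    sigma: float  # after clamping to [SIGMA_MIN, SIGMA_MAX]
    threshold: float
    valid_mask: np.ndarray  # Att >= threshold
    origin: tuple[float, float]  # image coords of grid cell (0, 0)
    step: float  # pixels per grid cell


def attention_map(
    l_c: np.ndarray | tuple[float, float],
    sigma_raw: float,
    grid_shape: tuple[int, int],
    origin: tuple[float, float] = (0.0, 0.0),
    step: float = 1.0,
    threshold: float = ATTENTION_THRESHOLD,
) -> AttentionMap:
    """Evaluate ``Att = exp(-d^2 / 2 sigma^2)`` on a candidate grid.

    ``grid_shape`` is (rows, cols); cell (i, j) sits at image position
    ``origin + step * (j, i)``.  ``sigma_raw`` is clamped to [3, 9] px and
    cells below ``threshold`` are masked invalid.
    """
    if grid_shape[0] < 1 or grid_shape[1] < 1:
        raise ValueError("grid_shape must be positive")
    sigma = float(np.clip(sigma_raw, SIGMA_MIN, SIGMA_MAX))
    l_c = np.asarray(l_c, dtype=float)
    rows, cols = grid_shape
    xs = origin[0] + step * np.arange(cols)
    ys = origin[1] + step * np.arange(rows)
    d2 = (xs[None, :] - l_c[0]) ** 2 + (ys[:, None] - l_c[1]) ** 2
    values = np.exp(-d2 / (2.0 * sigma * sigma))
    return AttentionMap(
        values=values,
        center=l_c,
        sigma=sigma,
        threshold=threshold,
        valid_mask=values >= threshold,
        origin=(float(origin[0]), float(origin[1])),
        step=float(step),
    )
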