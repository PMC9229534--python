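"""Quaternion attitude estimation with an acceleration-adaptive EKF.

A direct 4-state quaternion extended Kalman filter: the gyroscope drives the
prediction (exact quaternion exponential, renormalized every step), and the
accelerometer's gravity direction corrects tilt in the update.  The
measurement covariance R adapts to how far the recent acceleration norm is
from 1 G,

    σ_k² = 1/(N+1) · Σ_{i=k−N..k} (‖a_i‖ − 1)²,

so the filter trusts the accelerometer when the sensor is quasi-static
(‖a‖ ≈ 1 G → small R → strong correction) and ignores it under dynamic
motion (inertial acceleration inflates ‖a‖−1 → large R → the gyro carries
the estimate).  The norm statistic carries no axis information, so the same
σ² fills all three diagonal entries of R.  Yaw is unobservable from gravity
and is propagated by the gyro alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quat
from .errors import DataError
from .io import IMUStream


@dataclass
class EKFConfig:
    window_N: int = 40  # adaptive-R window, samples (100 ms at 400 Hz)
    gyro_noise_var: float = 1.0  # (deg/s)², also used for the process noise
    init_from_accel: bool = True
    init_P: float = 1e-2


@dataclass
class AdaptiveNoise:
    """Windowed variance estimate of the gravity-removed acceleration norm."""

    window_N: int
    sigma2: np.ndarray  # per-axis variances (all equal: the norm is axis-blind)

    @property
    def R(self) -> np.ndarray:
        return np.diag(self.sigma2)


@dataclass
class OrientationState:
    q_hat: np.ndarray = field(default_factory=lambda: quat.IDENTITY.copy())
    P: np.ndarray = field(default_factory=lambda: 1e-2 * np.eye(4))


@dataclass
class OrientationTrace:
    """Per-sample attitude estimate plus the adaptive variance that produced it."""

    timestamps: np.ndarray
    quaternions: np.ndarray  # (n, 4), sensor -> global
    sigma2: np.ndarray  # (n,), adaptive measurement variance

    @property
    def n(self) -> int:
        return self.timestamps.size

    def tilt_error_deg(self, reference: np.ndarray) -> np.ndarray:
        """Angle (deg) between estimated and reference gravity directions.

        ``reference``: (n, 4) true quaternions.  Ignores yaw, which gravity
        cannot observe.
        """
        ghat = np.array([0.0, 0.0, 1.0])
        out = np.empty(self.n)
        for k in range(self.n):
            est = quat.rotate_inverse(self.quaternions[k], ghat)
            ref = quat.rotate_inverse(reference[k], ghat)
            out[k] = np.degrees(np.arccos(np.clip(np.dot(est, ref), -1.0, 1.0)))
        return out

    def attitude_error_deg(self, reference: np.ndarray) -> np.ndarray:
        """Full geodesic attitude error (deg) against reference quaternions."""
        return np.degrees(
            [quat.angle_between(self.quaternions[k], reference[k]) for k in range(self.n)]
        )


def compute_adaptive_R(
    accel_norm_history: np.ndarray, k: int, window_N: int
) -> AdaptiveNoise:
    """Adaptive measurement covariance at sample k from the ‖a‖ history (G).

    Averages (‖a_i‖ − 1)² over i = k−N .. k; near the stream start the
    window truncates to the available samples.
    """
    h = np.asarray(accel_norm_history, dtype=float)
    if h.size == 0:
        raise DataError("empty acceleration-norm history")
    if not (0 <= k < h.size):
        raise DataError(f"index k={k} outside history of length {h.size}")
    lo = max(0, k - window_N)
    window = h[lo : k + 1]
    sigma2 = float(np.mean((window - 1.0) ** 2))
    return AdaptiveNoise(window_N=window_N, sigma2=np.full(3, sigma2))


def _xi(q: np.ndarray) -> np.ndarray:
    """∂(q ⊗ (0, ω))/∂ω — maps body-rate noise into quaternion space."""
    w, x, y, z = q
    return np.array([[-x, -y, -z], [w, -z, y], [z, w, -x], [-y, x, w]])


def _right_mult_matrix(d: np.ndarray) -> np.ndarray:
    """Matrix M with q ⊗ d = M q (right multiplication by d)."""
    w, x, y, z = d
    return np.array(
        [
            [w, -x, -y, -z],
            [x, w, z, -y],
            [y, -z, w, x],
            [z, y, -x, w],
        ]
    )


def ekf_predict(
    state: OrientationState, gyro_dps: np.ndarray, dt: float, gyro_noise_var: float = 1.0
) -> OrientationState:
    """Propagate the attitude by the measured body rate (deg/s) over dt."""
    if dt <= 0:
        raise DataError("dt must be positive")
    omega = np.radians(np.asarray(gyro_dps, dtype=float))
    delta = quat.exp_map(omega, dt)
    q_new = quat.normalize(quat.multiply(state.q_hat, delta))
    F = _right_mult_matrix(delta)
    G = 0.5 * dt * _xi(state.q_hat)
    Q = np.radians(1.0) ** 2 * gyro_noise_var * (G @ G.T)
    P = F @ state.P @ F.T + Q
    return OrientationState(q_hat=q_new, P=0.5 * (P + P.T))


def _gravity_jacobian(q: np.ndarray) -> np.ndarray:
    """Jacobian of h(q) = R(q)ᵀ ẑ with respect to (w, x, y, z)."""
    w, x, y, z = q
    return 2.0 * np.array(
        [
            [-y, z, -w, x],
            [x, w, z, y],
            [0.0, -2 * x, -2 * y, 0.0],
        ]
    )


def ekf_update(
    state: OrientationState, accel_g: np.ndarray, adaptive_noise: AdaptiveNoise
) -> OrientationState:
    """Correct tilt from the accelerometer's gravity direction.

    The measurement is the unit acceleration vector; the model is the global
    up-vector expressed in the sensor frame.  A zero-norm accelerometer
    sample is degenerate and leaves the state unchanged.  With huge R the
    correction vanishes; with R = 0 (exactly 1 G over the window) the update
    is applied through a pseudo-inverse, since gravity only constrains two
    of the three rotational degrees of freedom.
    """
    accel = np.asarray(accel_g, dtype=float)
    norm = np.linalg.norm(accel)
    if norm == 0.0:
        return state
    q, P = state.q_hat, state.P
    z = accel / norm
    h = quat.rotate_inverse(q, np.array([0.0, 0.0, 1.0]))
    H = _gravity_jacobian(q)
    S = H @ P @ H.T + adaptive_noise.R
    K = P @ H.T @ np.linalg.pinv(S, rcond=1e-12, hermitian=True)
    q_new = quat.normalize(q + K @ (z - h))
    P_new = (np.eye(4) - K @ H) @ P
    return OrientationState(q_hat=q_new, P=0.5 * (P_new + P_new.T))


def _init_attitude(accel_g: np.ndarray) -> np.ndarray:
    """Zero-yaw attitude whose gravity prediction matches the first sample."""
    norm = np.linalg.norm(accel_g)
    if norm == 0.0:
        return quat.IDENTITY.copy()
    return quat.shortest_arc(accel_g / norm, np.array([0.0, 0.0, 1.0]))


def estimate_orientation(stream: IMUStream, config: EKFConfig | None = None) -> OrientationTrace:
    """Run the adaptive-R EKF over a whole stream (causal, deterministic)."""
    cfg = config or EKFConfig()
    n = stream.n
    norms = stream.accel_norm()
    q0 = _init_attitude(stream.accel[0]) if cfg.init_from_accel else quat.IDENTITY.copy()
    state = OrientationState(q_hat=q0, P=cfg.init_P * np.eye(4))

    quats = np.empty((n, 4))
    sig2 = np.empty(n)
    noise0 = compute_adaptive_R(norms, 0, cfg.window_N)
    state = ekf_update(state, stream.accel[0], noise0)
    quats[0], sig2[0] = state.q_hat, noise0.sigma2[0]
    for k in range(1, n):
        dt = stream.timestamps[k] - stream.timestamps[k - 1]
        state = ekf_predict(state, stream.gyro[k], dt, cfg.gyro_noise_var)
        noise = compute_adaptive_R(norms, k, cfg.window_N)
        state = ekf_update(state, stream.accel[k], noise)
        quats[k], sig2[k] = state.q_hat, noise.sigma2[0]
    return OrientationTrace(timestamps=stream.timestamps.copy(), quaternions=quats, sigma2=sig2)
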