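"""Minimal unit-quaternion algebra used by the orientation filter.

Convention: quaternions are arrays ``(w, x, y, z)``; ``rotate(q, v)`` maps a
vector from the sensor (local) frame into the global frame, i.e. the
quaternion encodes the attitude of the sensor in the world.  The heavier
lifting in the simulator and in tests goes through
:class:`scipy.spatial.transform.Rotation`, which also acts as an independent
cross-check of these routines; the filter keeps its own algebra because it
needs analytic Jacobians with respect to the four components.
"""

from __future__ import annotations

import numpy as np

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q."""
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def normalize(q: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(q)
    if n == 0.0:
        raise ValueError("zero quaternion cannot be normalized")
    q = q / n
    # fix the double-cover sign so traces are continuous
    return q if q[0] >= 0.0 else -q


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate local-frame vector(s) v into the global frame.  v: (3,) or (n,3)."""
    return to_matrix(q) @ np.asarray(v, dtype=float).T if np.ndim(v) > 1 else to_matrix(q) @ v


def rotate_inverse(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate global-frame vector v into the local frame."""
    return to_matrix(q).T @ v


def to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        return IDENTITY.copy()
    half = 0.5 * angle_rad
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def exp_map(omega_rad: np.ndarray, dt: float) -> np.ndarray:
    """Exact quaternion exponential of a body rate ω (rad/s) over dt seconds."""
    theta = np.linalg.norm(omega_rad) * dt
    if theta < 1e-14:
        return IDENTITY.copy()
    return from_axis_angle(omega_rad, theta)


def log_map(q: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle, rad) of a unit quaternion."""
    q = q if q[0] >= 0 else -q
    v = q[1:]
    sin_half = np.linalg.norm(v)
    if sin_half < 1e-14:
        return np.zeros(3)
    angle = 2.0 * np.arctan2(sin_half, q[0])
    return v / sin_half * angle


def shortest_arc(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unit quaternion rotating unit vector u onto unit vector v (no twist)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = float(np.dot(u, v))
    if c < -1.0 + 1e-12:
        # antipodal: rotate 180 deg about any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        return from_axis_angle(axis, np.pi)
    axis = np.cross(u, v)
    q = np.concatenate([[1.0 + c], axis])
    return normalize(q)


def angle_between(p: np.ndarray, q: np.ndarray) -> float:
    """Geodesic angle (rad) between two attitudes."""
    d = multiply(conjugate(p), q)
    return float(np.linalg.norm(log_map(normalize(d))))
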