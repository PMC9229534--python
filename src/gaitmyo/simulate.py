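"""Synthetic two-IMU gait sessions with full ground truth.

The generator emulates the walking trials the estimation pipeline is built
for: an ankle-mounted inertial sensor that is exactly stationary while the
foot is on the ground and translates forward along a minimum-jerk profile
during swing, a shank angular-velocity waveform with the classic
mid-swing positive peak flanked by negative toe-off / heel-strike dips, and
surface-EMG surrogates built as activation-envelope-modulated broadband
noise (20–450 Hz band).  Every quantity the downstream stages estimate —
event times, stride lengths, per-sample attitude, activation envelopes — is
returned as ground truth, which makes the simulator the oracle for the test
suite.

Conventions
-----------
Global frame: X = walking direction, Z = up.  The simulated shank rotation
is placed about the sensor/global z-axis so that the sagittal-plane
angular-velocity waveform appears on gyro channel ``gz`` (the event
detector's default axis); the mounting-tilt parameter rotates the sensor
about x and is what makes gravity observability non-trivial for the
orientation filter.  This is a deliberate geometric simplification: the
event detector and the zero-velocity machinery only need the waveform shape
and the stationary-stance property, not an anatomically exact hinge axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from . import quat
from .errors import DataError
from .io import EMG_BAND_HZ, EMG_FS_DEFAULT, G_TO_MS2, IMU_FS_DEFAULT, BodySpec, EMGStream, IMUStream, Session

#: model feature columns, in canonical order
FEATURES = [
    "a_peak",
    "omega_peak",
    "v_peak",
    "l_stride",
    "stance_time",
    "swing_time",
    "bmi",
    "lower_limb_ratio",
]

#: model target columns (per-cycle %MVC average / peak for each muscle)
TARGETS = ["mvc_avg_rfm", "mvc_peak_rfm", "mvc_avg_ogm", "mvc_peak_ogm"]


@dataclass
class GaitSimParams:
    """Study conditions for one simulated walking trial.

    Defaults follow the walking protocol the pipeline targets: ~5 m of level
    walking (10 strides of 1.2 m), stride frequency 2 Hz inside the regular
    1–4 Hz walking band, quiet standing for one second before and after, a
    small sensor mounting tilt, and sensor noise at levels typical of a
    MEMS IMU (accelerometer 0.02 G, gyroscope 1 deg/s).
    """

    n_strides: int = 10
    stride_length: float = 1.2  # m
    cadence: float = 2.0  # stride frequency, Hz
    stance_fraction: float = 0.6
    tilt_deg: float = 5.0  # mounting tilt about x
    accel_noise_sd: float = 0.02  # G
    gyro_noise_sd: float = 1.0  # deg/s
    emg_noise_scale: float = 1.0  # overall EMG amplitude (arbitrary units)
    seed: int = 0
    imu_fs: float = IMU_FS_DEFAULT
    emg_fs: float = EMG_FS_DEFAULT
    pad_s: float = 1.0  # quiet standing before/after walking
    foot_clearance_m: float = 0.04

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise DataError("n_strides must be >= 1")
        if self.stride_length <= 0:
            raise DataError("stride_length must be positive")
        if not (1.0 <= self.cadence <= 4.0):
            raise DataError("cadence must lie in the regular walking band [1, 4] Hz")
        if not (0.0 < self.stance_fraction < 1.0):
            raise DataError("stance_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Everything the pipeline should recover, by construction."""

    timestamps: np.ndarray  # IMU time base, s
    hs_times: np.ndarray  # n_strides + 1 heel strikes (final one closes the last cycle)
    ff_times: np.ndarray
    to_times: np.ndarray
    ms_times: np.ndarray
    stride_lengths: np.ndarray  # m, one per stride
    ankle_trajectory: np.ndarray  # (n, 3) m, global frame
    orientation: np.ndarray  # (n, 4) unit quaternions, sensor -> global
    emg_timestamps: np.ndarray
    activation: dict[str, np.ndarray] = field(default_factory=dict)  # muscle -> envelope in [0,1]


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Quintic displacement profile: position, velocity and acceleration are
    zero at both ends; scale-free on s in [0, 1]."""
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _shank_gyro_profile(t: np.ndarray, p: GaitSimParams, events: dict) -> np.ndarray:
    """Sagittal shank angular velocity (deg/s): positive mid-swing peak,
    negative toe-off and heel-strike dips, near-zero during flat foot.

    Bump areas balance within each cycle so the shank angle oscillates
    instead of winding up.
    """
    T = 1.0 / p.cadence
    w_ms, w_to, w_hs = 0.06 * T, 0.05 * T, 0.05 * T
    swing_rotation_deg = 25.0  # forward shank sweep per swing
    a_ms = swing_rotation_deg / (w_ms * np.sqrt(2 * np.pi))
    a_dip = swing_rotation_deg / ((w_to + w_hs) * np.sqrt(2 * np.pi))
    omega = np.zeros_like(t)
    for t_ms in events["ms"]:
        omega += a_ms * _gauss(t, t_ms, w_ms)
    for t_to in events["to"]:
        omega -= a_dip * _gauss(t, t_to, w_to)
    # no impact dip at the very first heel strike (gait starts from standstill)
    for t_hs in events["hs"][1:]:
        omega -= a_dip * _gauss(t, t_hs, w_hs)
    return omega


def activation_envelope(phase: np.ndarray, muscle: str, baseline: float = 0.03) -> np.ndarray:
    """Phase-locked activation envelope in [0, 1] for a gait phase in [0, 1).

    Phase 0 is heel strike; stance nominally occupies the first ~60% of the
    cycle.  The rectus femoris fires briefly at weight acceptance (early
    stance) and again in early swing to bring the leg forward; during level
    walking it stays well below its maximum-effort level (peak ~0.26 of MVC
    here).  The gastrocnemius ramps up through late stance, peaking at
    push-off around 45–50% of the cycle.
    """
    phase = np.asarray(phase, dtype=float)
    if muscle == "RFM":
        bumps = [(0.22, 0.03, 0.05), (0.26, 0.70, 0.06)]
    elif muscle == "OGM":
        bumps = [(0.50, 0.45, 0.08)]
    else:
        raise DataError(f"unknown muscle {muscle!r}")
    env = np.full_like(phase, baseline)
    for amp, center, width in bumps:
        for wrap in (-1.0, 0.0, 1.0):  # wrapped Gaussians: envelope is periodic in phase
            env += amp * _gauss(phase, center + wrap, width)
    return np.clip(env, 0.0, 1.0)


def emg_from_activation(
    envelope: np.ndarray,
    fs: float = EMG_FS_DEFAULT,
    noise_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
    muscle: str = "RFM",
    side: str = "left",
    is_mvc_trial: bool = False,
    t0: float = 0.0,
) -> EMGStream:
    """Surrogate raw sEMG: envelope-modulated zero-mean broadband noise.

    The carrier is white Gaussian noise band-limited to the 20–450 Hz sEMG
    passband and rescaled to unit variance, so the windowed RMS of the
    output recovers ``noise_scale * envelope`` up to sampling error.
    """
    envelope = np.asarray(envelope, dtype=float)
    if envelope.size < 2:
        raise DataError("envelope must contain at least 2 samples")
    if np.any(envelope < 0) or np.any(envelope > 1):
        raise DataError("activation envelope must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(envelope.size)
    sos = butter(4, EMG_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    carrier = sosfiltfilt(sos, white)
    carrier /= carrier.std()
    t = t0 + np.arange(envelope.size) / fs
    return EMGStream(
        timestamps=t,
        signal=noise_scale * envelope * carrier,
        fs=fs,
        muscle=muscle,
        side=side,
        is_mvc_trial=is_mvc_trial,
    )


def imu_from_trajectory(
    positions: np.ndarray,
    orientations: np.ndarray,
    fs: float,
    placement: str = "ankle",
    side: str = "left",
    t0: float = 0.0,
) -> IMUStream:
    """Inverse sensor model: local-frame accelerometer (G) and gyroscope
    (deg/s) readings for a sampled trajectory and attitude history.

    accel_local(t) = R(q)ᵀ (p̈(t)/g + ẑ); the gyroscope is the body rate
    recovered from the discrete quaternion derivative via the log map, with
    central stencils in both cases.
    """
    positions = np.asarray(positions, dtype=float)
    orientations = np.asarray(orientations, dtype=float)
    n = positions.shape[0]
    if n < 3:
        raise DataError("need at least 3 samples to differentiate a trajectory")
    if orientations.shape != (n, 4):
        raise DataError("orientations must be (n, 4) quaternions matching positions")
    dt = 1.0 / fs
    vel = np.gradient(positions, dt, axis=0)
    acc_global = np.gradient(vel, dt, axis=0)  # m/s²
    ghat = np.array([0.0, 0.0, 1.0])
    accel_local = np.empty((n, 3))
    gyro_local = np.empty((n, 3))
    for k in range(n):
        q = orientations[k]
        accel_local[k] = quat.rotate_inverse(q, acc_global[k] / G_TO_MS2 + ghat)
        if 0 < k < n - 1:
            delta = quat.multiply(quat.conjugate(orientations[k - 1]), orientations[k + 1])
            gyro_local[k] = quat.log_map(quat.normalize(delta)) / (2 * dt)
    gyro_local[0] = gyro_local[1]
    gyro_local[-1] = gyro_local[-2]
    t = t0 + np.arange(n) * dt
    return IMUStream(
        timestamps=t,
        accel=accel_local,
        gyro=np.degrees(gyro_local),
        fs=fs,
        placement=placement,
        side=side,
    )


def simulate_mvc_trial(
    muscle: str,
    fs: float = EMG_FS_DEFAULT,
    noise_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
    duration_s: float = 5.0,
    side: str = "left",
) -> EMGStream:
    """Maximum-voluntary-contraction trial: ramp up, hold at full activation,
    release.  The envelope's maximum is exactly 1, so the trial defines the
    normalization reference."""
    t = np.arange(int(round(duration_s * fs))) / fs
    ramp, hold = 0.5, duration_s - 1.5
    env = np.clip(np.minimum(t / ramp, 1.0), 0.0, 1.0)
    env[t > ramp + hold] = np.clip(1.0 - (t[t > ramp + hold] - ramp - hold) / ramp, 0.05, 1.0)
    return emg_from_activation(
        env, fs=fs, noise_scale=noise_scale, seed=seed, muscle=muscle, side=side, is_mvc_trial=True
    )


def simulate_session(params: GaitSimParams) -> tuple[Session, GroundTruth]:
    """Generate a physically consistent walking session with ground truth.

    The ankle is exactly stationary during every stance phase and advances
    one stride length along x per swing on a minimum-jerk profile (with a
    small quartic foot-clearance lift).  Identical parameters — including
    the seed — give bit-identical output.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    T = 1.0 / p.cadence
    stance, swing = p.stance_fraction * T, (1 - p.stance_fraction) * T
    n = p.n_strides
    total = 2 * p.pad_s + n * T
    nt = int(round(total * p.imu_fs)) + 1
    t = np.arange(nt) / p.imu_fs

    hs = p.pad_s + np.arange(n + 1) * T
    to = hs[:-1] + stance
    ff = hs[:-1] + 0.1 * stance
    ms = to + 0.5 * swing  # mid-swing = swing-velocity peak of the symmetric profile
    events = {"hs": hs, "ff": ff, "to": to, "ms": ms}

    # ankle trajectory: piecewise stance plateaus + minimum-jerk swings
    x = np.zeros(nt)
    z = np.zeros(nt)
    for i in range(n):
        in_swing = (t >= to[i]) & (t < hs[i + 1])
        s = (t[in_swing] - to[i]) / swing
        x[in_swing] = (i + _minimum_jerk(s)) * p.stride_length
        z[in_swing] = p.foot_clearance_m * 16.0 * s**2 * (1 - s) ** 2
        x[t >= hs[i + 1]] = (i + 1) * p.stride_length
    positions = np.column_stack([x, np.zeros(nt), z])

    # attitude: sagittal oscillation about z on top of a fixed mounting tilt about x
    omega_z = _shank_gyro_profile(t, p, events)  # deg/s
    theta = np.concatenate([[0.0], np.cumsum(0.5 * (omega_z[1:] + omega_z[:-1])) / p.imu_fs])
    q_tilt = quat.from_axis_angle([1.0, 0.0, 0.0], np.radians(p.tilt_deg))
    orientation = np.empty((nt, 4))
    for k in range(nt):
        q_z = quat.from_axis_angle([0.0, 0.0, 1.0], np.radians(theta[k]))
        orientation[k] = quat.multiply(q_z, q_tilt)

    ankle = imu_from_trajectory(positions, orientation, p.imu_fs, placement="ankle")
    ankle.accel += rng.normal(0.0, p.accel_noise_sd, ankle.accel.shape)
    ankle.gyro += rng.normal(0.0, p.gyro_noise_sd, ankle.gyro.shape)

    # knee sensor: rides forward smoothly at constant tilt (unused by the
    # ankle-based feature chain, but part of the sensor set)
    knee_pos = np.column_stack([np.clip((t - hs[0]) / (n * T), 0, 1) * n * p.stride_length,
                                np.zeros(nt), np.zeros(nt)])
    knee_q = np.tile(q_tilt, (nt, 1))
    knee = imu_from_trajectory(knee_pos, knee_q, p.imu_fs, placement="knee")
    knee.accel += rng.normal(0.0, p.accel_noise_sd, knee.accel.shape)
    knee.gyro += rng.normal(0.0, p.gyro_noise_sd, knee.gyro.shape)

    # EMG on its own (faster) clock, same time origin
    nt_e = int(round(total * p.emg_fs)) + 1
    t_e = np.arange(nt_e) / p.emg_fs
    phase = ((t_e - hs[0]) / T) % 1.0
    walking = (t_e >= hs[0]) & (t_e <= hs[-1])
    activation = {}
    emg_streams = []
    for muscle in ("RFM", "OGM"):
        env = activation_envelope(phase, muscle)
        env[~walking] = 0.03  # quiet standing: baseline tone only
        activation[muscle] = env
        emg_streams.append(
            emg_from_activation(env, fs=p.emg_fs, noise_scale=p.emg_noise_scale,
                                seed=rng, muscle=muscle)
        )
        emg_streams.append(
            simulate_mvc_trial(muscle, fs=p.emg_fs, noise_scale=p.emg_noise_scale, seed=rng)
        )

    body = BodySpec(weight_kg=62.0, height_m=1.70, calf_length_cm=38.0, lower_limb_length_cm=88.0)
    session = Session(
        imu_streams=[ankle, knee],
        emg_streams=emg_streams,
        body=body,
        metadata={"trial": "simulated-walk", "cadence_hz": p.cadence, "seed": p.seed},
    )
    truth = GroundTruth(
        timestamps=t,
        hs_times=hs,
        ff_times=ff,
        to_times=to,
        ms_times=ms,
        stride_lengths=np.full(n, p.stride_length),
        ankle_trajectory=positions,
        orientation=orientation,
        emg_timestamps=t_e,
        activation=activation,
    )
    return session, truth


# ---------------------------------------------------------------------------
# Feature-level generator for model experiments
# ---------------------------------------------------------------------------

def simulate_feature_dataset(
    n_cycles: int = 2000,
    noise_frac: float = 0.05,
    seed: int = 0,
    n_subjects: int = 14,
) -> pd.DataFrame:
    """Per-cycle feature/target table for regression experiments.

    Draws gait cycles from a population of subjects (body metrics centred on
    a BMI of 21.5 ± 3.4 kg/m² and a lower-limb ratio of 0.43 ± 0.04, as in
    a typical young-adult cohort), derives the kinematic features from each
    cycle's cadence and stride, and builds the four %MVC targets as smooth
    functions of the features plus Gaussian noise with standard deviation
    ``noise_frac`` of each target's clean range.  Clean targets are kept in
    ``true_*`` columns.
    """
    rng = np.random.default_rng(seed)
    subj = rng.integers(0, n_subjects, n_cycles)
    bmi_pop = np.clip(rng.normal(21.5, 3.4, n_subjects), 16.0, 35.0)
    ratio_pop = np.clip(rng.normal(0.43, 0.04, n_subjects), 0.30, 0.55)
    speed_pop = rng.normal(0.0, 0.25, n_subjects)  # subject pace preference

    cadence = np.clip(rng.normal(1.9 + 0.4 * speed_pop[subj], 0.25), 1.0, 3.2)
    T = 1.0 / cadence
    stance_frac = np.clip(rng.normal(0.62 - 0.02 * (cadence - 1.9), 0.015), 0.5, 0.75)
    stance_time = stance_frac * T
    swing_time = (1 - stance_frac) * T
    l_stride = np.clip(rng.normal(0.55 + 0.38 * cadence, 0.08), 0.35, 2.2)
    v_peak = 1.875 * l_stride / swing_time * rng.normal(1.0, 0.03, n_cycles)
    a_peak = np.sqrt((5.77 * l_stride / swing_time**2 / G_TO_MS2) ** 2 + 1.0) * rng.normal(
        1.0, 0.05, n_cycles
    )
    omega_peak = 166.0 * cadence * rng.normal(1.0, 0.05, n_cycles)

    df = pd.DataFrame(
        {
            "a_peak": a_peak,
            "omega_peak": omega_peak,
            "v_peak": v_peak,
            "l_stride": l_stride,
            "stance_time": stance_time,
            "swing_time": swing_time,
            "bmi": bmi_pop[subj],
            "lower_limb_ratio": ratio_pop[subj],
        }
    )
    df.insert(0, "cycle_index", np.arange(n_cycles))

    # smooth, mildly nonlinear activity surfaces (in %MVC)
    effort = 0.08 * v_peak + 0.35 * l_stride + 0.06 * (df["bmi"] - 21.5)
    clean = {
        "mvc_avg_rfm": 10 + 7 * np.tanh(effort - 0.6) + 0.02 * omega_peak * swing_time
        - 12 * (df["lower_limb_ratio"] - 0.43),
        "mvc_peak_rfm": 22 + 12 * np.tanh(effort - 0.5) + 1.5 * a_peak,
        "mvc_avg_ogm": 18 + 10 * np.tanh(1.2 * effort - 0.7) + 6 * stance_time
        + 10 * (df["lower_limb_ratio"] - 0.43),
        "mvc_peak_ogm": 35 + 16 * np.tanh(1.1 * effort - 0.6) + 0.01 * omega_peak,
    }
    for name, y in clean.items():
        y = np.asarray(y, dtype=float)
        rng_y = float(np.ptp(y))
        df["true_" + name] = y
        df[name] = y + rng.normal(0.0, noise_frac * rng_y, n_cycles)
    return df
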