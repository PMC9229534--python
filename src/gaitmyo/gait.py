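"""Gait-event detection and per-cycle kinematics from the ankle IMU.

The chain implemented here turns a shank/ankle inertial stream into one
kinematic record per gait cycle:

1. events from the sagittal angular velocity (mid-swing positive peak,
   flanking negative minima at toe-off and heel strike, flat-foot from a
   sustained quiet interval);
2. attitude from the adaptive-R EKF, then rotation of the accelerometer
   into the global frame and removal of gravity;
3. zero-velocity-update (ZUPT) integration: horizontal velocity accumulates
   only while the foot is airborne and is pinned to zero while it is known
   to be on the ground, which cancels integration drift once per stride;
4. walking distance as the time integral of the horizontal speed (a
   staircase curve for normal gait), stride lengths as its increments
   between consecutive heel strikes, with strides of 30 cm or less
   discarded as missteps;
5. swing-phase peaks of ‖a‖ and ‖ω‖ plus stance/swing durations.

Event times are timestamps in seconds throughout; sample lookup is
nearest-neighbour.

Cycle bookkeeping: a gait cycle runs heel strike → next heel strike.  The
first detectable swing of a recording precedes the first detected heel
strike (there is no mid-swing peak before it), so the stride arriving at
the first heel strike carries ``cycle_index = -1`` and has no stance time;
complete cycles are indexed 0, 1, ... from the first detected heel strike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import quat
from .errors import ConfigError, DataError
from .io import G_TO_MS2, IMUStream, Session
from .orientation import EKFConfig, OrientationTrace, estimate_orientation


@dataclass
class GaitConfig:
    sagittal_axis: int = 2  # gyro channel carrying the sagittal-plane rate
    min_swing_peak: float = 80.0  # deg/s, minimum mid-swing peak height
    dip_prominence: float = 30.0  # deg/s, prominence of the TO/HS minima
    flat_threshold: float = 10.0  # deg/s, |ω| bound defining flat foot
    flat_hold: float = 0.05  # s the gyro must stay quiet for flat foot
    zero_interval: str = "stance-only"  # "stance-only" (FF→TO) or "as-printed" (HS→MS)
    min_stride_m: float = 0.30  # misstep filter: strides ≤ this are discarded
    ekf: EKFConfig = field(default_factory=EKFConfig)

    def __post_init__(self) -> None:
        if self.sagittal_axis not in (0, 1, 2):
            raise ConfigError(f"sagittal_axis must be 0, 1 or 2, got {self.sagittal_axis}")
        if self.zero_interval not in ("stance-only", "as-printed"):
            raise ConfigError(
                f"zupt.zero_interval must be 'stance-only' or 'as-printed', got {self.zero_interval!r}"
            )


@dataclass
class GaitEvents:
    """Detected event times (s).  ``to_times[i]``/``ms_times[i]`` belong to the
    cycle starting at ``hs_times[i]``; ``lead_to``/``lead_ms`` describe the
    orphan swing that closes at the first heel strike."""

    hs_times: np.ndarray
    to_times: np.ndarray
    ms_times: np.ndarray
    ff_times: np.ndarray | None = None
    lead_to: float = np.nan
    lead_ms: float = np.nan

    def __post_init__(self) -> None:
        self.hs_times = np.atleast_1d(np.asarray(self.hs_times, dtype=float))
        self.to_times = np.atleast_1d(np.asarray(self.to_times, dtype=float))
        self.ms_times = np.atleast_1d(np.asarray(self.ms_times, dtype=float))
        if self.hs_times.size and np.any(np.diff(self.hs_times) <= 0):
            raise DataError("heel-strike times must be strictly increasing")
        if self.ff_times is None:
            self.ff_times = np.full(self.hs_times.size, np.nan)
        else:
            self.ff_times = np.atleast_1d(np.asarray(self.ff_times, dtype=float))

    @property
    def n_hs(self) -> int:
        return self.hs_times.size

    @property
    def n_cycles(self) -> int:
        """Complete cycles: need a starting HS, its TO, and the closing HS."""
        return min(self.to_times.size, max(self.n_hs - 1, 0))

    @property
    def is_empty(self) -> bool:
        return self.n_hs == 0

    def all_to(self) -> np.ndarray:
        head = [] if np.isnan(self.lead_to) else [self.lead_to]
        return np.concatenate([head, self.to_times])

    def all_ms(self) -> np.ndarray:
        head = [] if np.isnan(self.lead_ms) else [self.lead_ms]
        return np.concatenate([head, self.ms_times])

    def swings(self) -> pd.DataFrame:
        """One row per swing: (cycle_index, to, ms, hs_close)."""
        rows = []
        if not np.isnan(self.lead_to) and self.n_hs:
            rows.append((-1, self.lead_to, self.lead_ms, self.hs_times[0]))
        for i in range(self.n_cycles):
            rows.append((i, self.to_times[i], self.ms_times[i], self.hs_times[i + 1]))
        return pd.DataFrame(rows, columns=["cycle_index", "to", "ms", "hs_close"])


def _first_quiet_run(absg: np.ndarray, t: np.ndarray, start_idx: int, thr: float, hold_n: int):
    below = absg[start_idx:] < thr
    run = 0
    for j, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= hold_n:
            return t[start_idx + j - hold_n + 1]
    return np.nan


def detect_gait_events(stream: IMUStream, config: GaitConfig | None = None) -> GaitEvents:
    """Detect HS / FF / TO / MS from the sagittal shank angular velocity.

    Grammar: mid-swing = positive peak above ``min_swing_peak``; toe-off =
    nearest prominent negative minimum before it; heel strike = nearest
    prominent negative minimum after it; flat foot = start of the first
    interval after a heel strike where |ω| stays below ``flat_threshold``
    for ``flat_hold`` seconds.  Streams with no swing peaks yield an empty
    event set (standing is not an error); incomplete leading/trailing
    swings are dropped.
    """
    cfg = config or GaitConfig()
    g = stream.gyro[:, cfg.sagittal_axis]
    t = stream.timestamps
    ms_idx, _ = find_peaks(g, height=cfg.min_swing_peak, prominence=0.5 * cfg.min_swing_peak)
    if ms_idx.size == 0:
        return GaitEvents(
            hs_times=np.empty(0), to_times=np.empty(0), ms_times=np.empty(0),
            ff_times=np.empty(0),
        )
    dip_idx, _ = find_peaks(-g, prominence=cfg.dip_prominence)
    swings = []  # (to_idx, ms_idx, hs_idx)
    last_hs = -1
    for m in ms_idx:
        before = dip_idx[dip_idx < m]
        after = dip_idx[dip_idx > m]
        if before.size == 0 or after.size == 0:
            continue  # incomplete leading/trailing swing
        to_i, hs_i = int(before[-1]), int(after[0])
        if to_i <= last_hs:  # two swing peaks sharing one dip: keep the first
            continue
        swings.append((to_i, m, hs_i))
        last_hs = hs_i
    if not swings:
        return GaitEvents(
            hs_times=np.empty(0), to_times=np.empty(0), ms_times=np.empty(0),
            ff_times=np.empty(0),
        )

    hs = np.array([t[s[2]] for s in swings])
    hold_n = max(2, int(round(cfg.flat_hold * stream.fs)))
    absg = np.abs(g)
    ff = np.array(
        [_first_quiet_run(absg, t, s[2], cfg.flat_threshold, hold_n) for s in swings]
    )
    # swing i closes at hs[i]; its TO/MS belong to the cycle starting at hs[i-1]
    to_all = np.array([t[s[0]] for s in swings])
    ms_all = np.array([t[s[1]] for s in swings])
    return GaitEvents(
        hs_times=hs,
        to_times=to_all[1:],
        ms_times=ms_all[1:],
        ff_times=ff,
        lead_to=to_all[0],
        lead_ms=ms_all[0],
    )


def segment_phases(events: GaitEvents) -> pd.DataFrame:
    """Per-cycle stance and swing durations.

    stance(i) = TO(i) − HS(i); swing(i) = HS(i+1) − TO(i).  The last cycle
    needs a closing heel strike, otherwise it is dropped.  Empty events give
    an empty table.
    """
    rows = []
    for i in range(events.n_cycles):
        rows.append(
            (
                i,
                events.to_times[i] - events.hs_times[i],
                events.hs_times[i + 1] - events.to_times[i],
            )
        )
    df = pd.DataFrame(rows, columns=["cycle_index", "stance_time", "swing_time"])
    if len(df) and (df["stance_time"].le(0).any() or df["swing_time"].le(0).any()):
        raise DataError("event ordering violated: non-positive stance or swing duration")
    return df


def swing_peaks(stream: IMUStream, events: GaitEvents) -> pd.DataFrame:
    """Peak ‖a‖ (G) and ‖ω‖ (deg/s) over each swing's closed [TO, HS] range."""
    a_norm = stream.accel_norm()
    w_norm = np.linalg.norm(stream.gyro, axis=1)
    t = stream.timestamps
    rows = []
    for _, sw in events.swings().iterrows():
        sel = (t >= sw["to"]) & (t <= sw["hs_close"])
        if sel.sum() < 2:
            rows.append((int(sw["cycle_index"]), np.nan, np.nan, False))
            continue
        rows.append((int(sw["cycle_index"]), float(a_norm[sel].max()), float(w_norm[sel].max()), True))
    return pd.DataFrame(rows, columns=["cycle_index", "a_peak", "omega_peak", "valid"])


def to_global_frame(stream: IMUStream, trace: OrientationTrace) -> np.ndarray:
    """Gravity-free acceleration in the global frame, m/s² (n, 3).

    a_global = R(q̂) a_local − ẑ, scaled from G to m/s².  This is the only
    place acceleration leaves G units.
    """
    if trace.n != stream.n:
        raise DataError(
            f"orientation trace ({trace.n}) not sample-aligned with stream ({stream.n})"
        )
    ghat = np.array([0.0, 0.0, 1.0])
    out = np.empty((stream.n, 3))
    for k in range(stream.n):
        out[k] = quat.rotate(trace.quaternions[k], stream.accel[k]) - ghat
    return out * G_TO_MS2


@dataclass
class VelocityTrace:
    timestamps: np.ndarray
    v_x: np.ndarray
    v_y: np.ndarray
    v_norm: np.ndarray
    zeroed_mask: np.ndarray


@dataclass
class DistanceTrace:
    timestamps: np.ndarray
    X: np.ndarray  # cumulative walking distance, m


def _live_intervals(events: GaitEvents, mode: str, t_end: float) -> list[tuple[float, float]]:
    """Open intervals where the velocity integrator runs.

    "as-printed": live between each mid-swing and the following heel strike
    (the zero interval extends from heel strike to the *next* mid-swing,
    i.e. through stance and the first half of swing).
    "stance-only": live from each toe-off until the following flat-foot
    (fall back to the next heel strike plus the quiet hold if no flat-foot
    was detected), so the whole swing contributes.
    """
    hs = events.hs_times
    ff = events.ff_times
    out = []
    if mode == "as-printed":
        for m in events.all_ms():
            nxt = hs[hs > m]
            if nxt.size:
                out.append((m, float(nxt[0])))
    else:
        for to in events.all_to():
            nxt_ff = ff[~np.isnan(ff) & (ff > to)]
            nxt_hs = hs[hs > to]
            if nxt_ff.size:
                out.append((to, float(nxt_ff[0])))
            elif nxt_hs.size:
                out.append((to, float(nxt_hs[0])))
    return out


def zupt_velocity(
    a_global: np.ndarray,
    events: GaitEvents,
    fs: float,
    t0: float = 0.0,
    zero_interval: str = "stance-only",
) -> VelocityTrace:
    """Zero-velocity-update horizontal velocity from global acceleration.

    Horizontal components accumulate a·dt inside each live interval,
    restarting from zero at the interval's start (this is what cancels
    drift); the norm is forced to exactly zero outside live intervals and
    the mask marks those samples.  No mid-swing events → all-zero trace.
    """
    a_global = np.asarray(a_global, dtype=float)
    n = a_global.shape[0]
    t = t0 + np.arange(n) / fs
    dt = 1.0 / fs
    vx = np.zeros(n)
    vy = np.zeros(n)
    zeroed = np.ones(n, dtype=bool)
    for start, end in _live_intervals(events, zero_interval, t[-1] if n else 0.0):
        sel = (t > start) & (t < end)
        if not np.any(sel):
            continue
        vx[sel] = np.cumsum(a_global[sel, 0]) * dt
        vy[sel] = np.cumsum(a_global[sel, 1]) * dt
        zeroed[sel] = False
    v_norm = np.where(zeroed, 0.0, np.hypot(vx, vy))
    return VelocityTrace(timestamps=t, v_x=vx, v_y=vy, v_norm=v_norm, zeroed_mask=zeroed)


def walking_distance(vel: VelocityTrace, fs: float) -> DistanceTrace:
    """Cumulative walking distance X(t) = Σ ‖v‖ dt — the staircase curve."""
    X = np.cumsum(vel.v_norm) / fs
    return DistanceTrace(timestamps=vel.timestamps.copy(), X=X)


def stride_lengths(
    distance: DistanceTrace,
    hs_times: np.ndarray | GaitEvents,
    min_length_m: float = 0.30,
) -> pd.DataFrame:
    """Stride lengths from walking-distance increments between heel strikes.

    The first stride is the distance accumulated up to the first heel
    strike; later strides are consecutive increments.  Strides of
    ``min_length_m`` or less are discarded as missteps and the running
    stride number advances only for retained strides.  Columns:
    ``cycle_index`` (cycle traversed, −1 for the pre-cycle stride),
    ``hs_time``, ``l_stride``, ``retained``, ``stride`` (1-based number for
    retained rows, pandas NA otherwise).
    """
    if isinstance(hs_times, GaitEvents):
        hs_times = hs_times.hs_times
    hs_times = np.atleast_1d(np.asarray(hs_times, dtype=float))
    if hs_times.size == 0:
        return pd.DataFrame(columns=["cycle_index", "hs_time", "l_stride", "retained", "stride"])
    idx = np.clip(
        np.searchsorted(distance.timestamps, hs_times, side="right") - 1, 0, len(distance.X) - 1
    )
    x_at_hs = distance.X[idx]
    l_raw = np.diff(np.concatenate([[0.0], x_at_hs]))
    retained = l_raw > min_length_m
    stride_no = np.where(retained, np.cumsum(retained), 0)
    df = pd.DataFrame(
        {
            "cycle_index": np.arange(hs_times.size) - 1,
            "hs_time": hs_times,
            "l_stride": l_raw,
            "retained": retained,
            "stride": pd.array(
                [int(s) if r else pd.NA for s, r in zip(stride_no, retained)], dtype="Int64"
            ),
        }
    )
    return df


def extract_gait_features(session: Session, config: GaitConfig | None = None) -> pd.DataFrame:
    """Full ankle-IMU chain: one kinematic record per retained stride.

    Composes event detection → EKF orientation → global-frame acceleration →
    ZUPT velocity → walking distance → stride lengths → swing peaks and
    phase durations.  Deterministic for a fixed session and configuration.
    Returns columns cycle_index, hs_time, l_stride, a_peak, omega_peak,
    v_peak, stance_time, swing_time (NaN stance for the pre-cycle stride).
    """
    cfg = config or GaitConfig()
    stream = session.imu("ankle")
    events = detect_gait_events(stream, cfg)
    cols = [
        "cycle_index", "hs_time", "l_stride", "a_peak", "omega_peak",
        "v_peak", "stance_time", "swing_time",
    ]
    if events.is_empty:
        return pd.DataFrame(columns=cols)
    trace = estimate_orientation(stream, cfg.ekf)
    a_glob = to_global_frame(stream, trace)
    vel = zupt_velocity(
        a_glob, events, stream.fs, t0=stream.timestamps[0], zero_interval=cfg.zero_interval
    )
    dist = walking_distance(vel, stream.fs)
    strides = stride_lengths(dist, events, cfg.min_stride_m)

    peaks = swing_peaks(stream, events)
    swings = events.swings()
    v_peaks = []
    t = vel.timestamps
    for _, sw in swings.iterrows():
        sel = (t >= sw["to"]) & (t <= sw["hs_close"])
        v_peaks.append(float(vel.v_norm[sel].max()) if np.any(sel) else np.nan)
    peaks = peaks.assign(v_peak=v_peaks)
    swing_dur = (swings["hs_close"] - swings["to"]).to_numpy()
    peaks = peaks.assign(swing_time=swing_dur)

    phases = segment_phases(events)[["cycle_index", "stance_time"]]
    df = strides.merge(peaks, on="cycle_index", how="left").merge(
        phases, on="cycle_index", how="left"
    )
    df = df[df["retained"] & df["valid"].fillna(False)]
    return df[cols].reset_index(drop=True)
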