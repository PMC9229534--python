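"""Sensor-stream data model and session I/O.

A *session* is one recording: IMU streams (tri-axial acceleration in G and
angular velocity in deg/s, nominally 400 Hz), raw sEMG streams (nominally
1000 Hz, including maximum-voluntary-contraction trials), and the subject's
body measurements.  No standard container format exists for this sensor
pair, so streams are stored as plain CSV with a one-line ``#``-comment
metadata header — human-inspectable and loss-free:

``imu_<placement>_<side>.csv``::

    # fs=400 placement=ankle side=left
    t,ax,ay,az,gx,gy,gz
    0.0000,0.01,-0.02,0.99,0.1,0.0,-0.3
    ...

``emg_<muscle>_<side>[_mvc].csv``::

    # fs=1000 muscle=RFM side=left mvc=false
    t,emg
    ...

plus a ``meta.json`` with the body measurements and free-form metadata.
Acceleration stays in G end-to-end; conversion to m/s² happens only inside
kinematic computations.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError

G_TO_MS2 = 9.80665

IMU_FS_DEFAULT = 400.0  # Hz, nominal IMU rate
EMG_FS_DEFAULT = 1000.0  # Hz, nominal sEMG rate
EMG_BAND_HZ = (20.0, 450.0)  # analog passband of the sEMG front-end

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
EMG_COLUMNS = ["t", "emg"]

_PLACEMENTS = ("ankle", "knee")
_SIDES = ("left", "right")
_MUSCLES = ("RFM", "OGM")


def _check_timebase(t: np.ndarray, fs: float, label: str) -> None:
    if t.size == 0:
        raise DataError(f"{label}: empty stream")
    if not np.all(np.isfinite(t)):
        row = int(np.flatnonzero(~np.isfinite(t))[0])
        raise DataError(f"{label}: non-finite timestamp at row {row}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise DataError(f"{label}: timestamps not strictly increasing at row {row}")
    if fs <= 0:
        raise DataError(f"{label}: fs must be positive, got {fs}")
    if t.size >= 2:
        nominal = 1.0 / fs
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            row = int(np.flatnonzero(np.abs(dt - nominal) > 0.01 * nominal)[0]) + 1
            raise DataError(
                f"{label}: sample interval deviates >1% from 1/fs at row {row} "
                f"(dt={dt[row - 1]:.6g}, expected {nominal:.6g})"
            )


@dataclass
class IMUStream:
    """Uniformly sampled inertial stream: accel in G, gyro in deg/s."""

    timestamps: np.ndarray
    accel: np.ndarray  # (n, 3) in G
    gyro: np.ndarray  # (n, 3) in deg/s
    fs: float = IMU_FS_DEFAULT
    placement: str = "ankle"
    side: str = "left"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        label = f"IMU[{self.placement}/{self.side}]"
        if self.placement not in _PLACEMENTS:
            raise DataError(f"{label}: unknown placement {self.placement!r}")
        if self.side not in _SIDES:
            raise DataError(f"{label}: unknown side {self.side!r}")
        if self.accel.shape != (self.timestamps.size, 3) or self.gyro.shape != (
            self.timestamps.size,
            3,
        ):
            raise DataError(f"{label}: accel/gyro must be (n, 3) matching timestamps")
        if not (np.all(np.isfinite(self.accel)) and np.all(np.isfinite(self.gyro))):
            raise DataError(f"{label}: non-finite samples")
        _check_timebase(self.timestamps, self.fs, label)

    @property
    def n(self) -> int:
        return self.timestamps.size

    def accel_norm(self) -> np.ndarray:
        """Per-sample acceleration magnitude in G (the ‖a_i‖ used downstream)."""
        return np.linalg.norm(self.accel, axis=1)


@dataclass
class EMGStream:
    """Raw surface-EMG stream (arbitrary amplitude units)."""

    timestamps: np.ndarray
    signal: np.ndarray
    fs: float = EMG_FS_DEFAULT
    muscle: str = "RFM"
    side: str = "left"
    is_mvc_trial: bool = False

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        label = f"EMG[{self.muscle}/{self.side}{'/mvc' if self.is_mvc_trial else ''}]"
        if self.muscle not in _MUSCLES:
            raise DataError(f"{label}: unknown muscle {self.muscle!r}")
        if self.side not in _SIDES:
            raise DataError(f"{label}: unknown side {self.side!r}")
        if self.signal.shape != self.timestamps.shape:
            raise DataError(f"{label}: signal length must match timestamps")
        if not np.all(np.isfinite(self.signal)):
            raise DataError(f"{label}: non-finite samples")
        _check_timebase(self.timestamps, self.fs, label)

    @property
    def n(self) -> int:
        return self.timestamps.size


@dataclass
class BodySpec:
    """Subject body measurements feeding BMI and the lower-limb ratio."""

    weight_kg: float
    height_m: float
    calf_length_cm: float
    lower_limb_length_cm: float

    def __post_init__(self) -> None:
        vals = (self.weight_kg, self.height_m, self.calf_length_cm, self.lower_limb_length_cm)
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise DataError(f"body measurements must be positive and finite: {vals}")
        if self.calf_length_cm >= self.lower_limb_length_cm:
            raise DataError("calf length must be shorter than the lower-limb length")


@dataclass
class Session:
    """One recording: IMU + EMG streams plus body measurements."""

    imu_streams: list[IMUStream] = field(default_factory=list)
    emg_streams: list[EMGStream] = field(default_factory=list)
    body: BodySpec | None = None
    metadata: dict = field(default_factory=dict)

    def imu(self, placement: str = "ankle", side: str | None = None) -> IMUStream:
        for s in self.imu_streams:
            if s.placement == placement and (side is None or s.side == side):
                return s
        raise DataError(f"no IMU stream with placement={placement!r} side={side!r}")

    def emg(self, muscle: str, side: str | None = None, mvc: bool = False) -> EMGStream:
        for s in self.emg_streams:
            if s.muscle == muscle and s.is_mvc_trial == mvc and (side is None or s.side == side):
                return s
        raise DataError(f"no EMG stream with muscle={muscle!r} mvc={mvc}")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _format_meta(pairs: dict) -> str:
    return "# " + " ".join(f"{k}={v}" for k, v in pairs.items())


def _parse_meta(line: str, path: Path) -> dict:
    if not line.startswith("#"):
        raise FormatError(f"{path}: missing '# key=value ...' metadata comment line")
    out = {}
    for token in line.lstrip("#").split():
        if "=" not in token:
            raise FormatError(f"{path}: malformed metadata token {token!r}")
        k, v = token.split("=", 1)
        out[k] = v
    return out


def _read_csv(path: Path, columns: list[str]) -> tuple[dict, pd.DataFrame]:
    with open(path) as fh:
        meta = _parse_meta(fh.readline().strip(), path)
        df = pd.read_csv(fh, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    return meta, df


def _check_declared_fs(t: np.ndarray, declared: float, path: Path) -> None:
    if t.size >= 2:
        inferred = 1.0 / float(np.median(np.diff(t)))
        if abs(inferred - declared) > 0.01 * declared:
            raise DataError(
                f"{path}: declared fs={declared} Hz but median sample interval implies "
                f"{inferred:.2f} Hz (>1% off); refusing to resample silently"
            )


def read_imu_csv(path: str | Path) -> IMUStream:
    path = Path(path)
    meta, df = _read_csv(path, IMU_COLUMNS)
    fs = float(meta.get("fs", IMU_FS_DEFAULT))
    t = df["t"].to_numpy(float)
    dup = np.flatnonzero(np.diff(t) <= 0)
    if dup.size:
        raise DataError(f"{path}: timestamps not strictly increasing at row {int(dup[0]) + 2}")
    _check_declared_fs(t, fs, path)
    return IMUStream(
        timestamps=t,
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
        fs=fs,
        placement=meta.get("placement", "ankle"),
        side=meta.get("side", "left"),
    )


def read_emg_csv(path: str | Path) -> EMGStream:
    path = Path(path)
    meta, df = _read_csv(path, EMG_COLUMNS)
    fs = float(meta.get("fs", EMG_FS_DEFAULT))
    t = df["t"].to_numpy(float)
    dup = np.flatnonzero(np.diff(t) <= 0)
    if dup.size:
        raise DataError(f"{path}: timestamps not strictly increasing at row {int(dup[0]) + 2}")
    _check_declared_fs(t, fs, path)
    return EMGStream(
        timestamps=t,
        signal=df["emg"].to_numpy(float),
        fs=fs,
        muscle=meta.get("muscle", "RFM"),
        side=meta.get("side", "left"),
        is_mvc_trial=meta.get("mvc", "false").lower() == "true",
    )


def _write_csv(path: Path, meta: dict, frame: pd.DataFrame) -> None:
    buf = _io.StringIO()
    # %.17g round-trips IEEE doubles exactly
    frame.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(_format_meta(meta) + "\n" + buf.getvalue())


def write_imu_csv(stream: IMUStream, path: str | Path) -> None:
    frame = pd.DataFrame(
        np.column_stack([stream.timestamps, stream.accel, stream.gyro]), columns=IMU_COLUMNS
    )
    meta = {"fs": f"{stream.fs:.17g}", "placement": stream.placement, "side": stream.side}
    _write_csv(Path(path), meta, frame)


def write_emg_csv(stream: EMGStream, path: str | Path) -> None:
    frame = pd.DataFrame({"t": stream.timestamps, "emg": stream.signal})
    meta = {
        "fs": f"{stream.fs:.17g}",
        "muscle": stream.muscle,
        "side": stream.side,
        "mvc": str(stream.is_mvc_trial).lower(),
    }
    _write_csv(Path(path), meta, frame)


def write_session(session: Session, directory: str | Path) -> list[Path]:
    """Write a session directory; returns the list of files written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for s in session.imu_streams:
        p = directory / f"imu_{s.placement}_{s.side}.csv"
        write_imu_csv(s, p)
        written.append(p)
    for s in session.emg_streams:
        suffix = "_mvc" if s.is_mvc_trial else ""
        p = directory / f"emg_{s.muscle}_{s.side}{suffix}.csv"
        write_emg_csv(s, p)
        written.append(p)
    meta = dict(session.metadata)
    if session.body is not None:
        meta["body"] = {
            "weight_kg": session.body.weight_kg,
            "height_m": session.body.height_m,
            "calf_length_cm": session.body.calf_length_cm,
            "lower_limb_length_cm": session.body.lower_limb_length_cm,
        }
    p = directory / "meta.json"
    p.write_text(json.dumps(meta, indent=1))
    written.append(p)
    return written


def read_session(directory: str | Path) -> Session:
    """Read a session directory written in the package's CSV dialect."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"{directory}: not a directory")
    imu_files = sorted(directory.glob("imu_*.csv"))
    emg_files = sorted(directory.glob("emg_*.csv"))
    if not imu_files:
        raise FormatError(
            f"{directory}: no streams found; expected imu_<placement>_<side>.csv "
            "(and optionally emg_<muscle>_<side>[_mvc].csv, meta.json)"
        )
    session = Session(
        imu_streams=[read_imu_csv(p) for p in imu_files],
        emg_streams=[read_emg_csv(p) for p in emg_files],
    )
    meta_path = directory / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        body = meta.pop("body", None)
        if body is not None:
            session.body = BodySpec(**body)
        session.metadata = meta
    return session


def align_clock(stream_a, stream_b) -> float:
    """Start-time offset (s) of stream_b relative to stream_a on the shared clock.

    Both streams carry timestamps on one clock (hardware-synchronized at the
    source), so alignment is purely timestamp arithmetic; downstream per-cycle
    EMG aggregation indexes by IMU event times with nearest-sample lookup.
    """
    a0, a1 = stream_a.timestamps[0], stream_a.timestamps[-1]
    b0, b1 = stream_b.timestamps[0], stream_b.timestamps[-1]
    if b0 > a1 or a0 > b1:
        raise AlignmentError(
            f"streams do not overlap in time: [{a0}, {a1}] vs [{b0}, {b1}]"
        )
    return float(b0 - a0)
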