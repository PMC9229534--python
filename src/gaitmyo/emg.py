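"""Surface-EMG processing: band-pass, RMS envelope, %MVC targets.

The training targets of the activity model are built offline from raw sEMG:
zero-phase band-pass over the 20–450 Hz sensor passband, a sliding
root-mean-square envelope with a 100 ms window, normalization by the peak
RMS of the subject's maximum-voluntary-contraction trial, and per-gait-cycle
aggregation into average and peak %MVC.  The MVC trial runs through the
identical filter + RMS chain as the walking trials.  Rectification is
implicit in the squaring; no separate rectify step is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import DataError
from .io import BodySpec, EMGStream

RMS_WINDOW_MS = 100.0  # total window length of the RMS envelope


@dataclass
class EMGEnvelope:
    """RMS envelope of a filtered EMG stream, optionally %MVC-normalized."""

    timestamps: np.ndarray
    rms: np.ndarray
    muscle: str
    side: str
    pct_mvc: np.ndarray | None = None


@dataclass
class BodyMetrics:
    """Subject covariates for the activity model."""

    bmi: float  # kg/m²
    lower_limb_ratio: float  # calf length / lower-limb length


def bandpass_filter(stream: EMGStream, low_hz: float = 20.0, high_hz: float = 450.0) -> EMGStream:
    """Zero-phase 4th-order band-pass; removes DC, preserves length.

    The band reproduces in software the analog front-end applied to real
    recordings, so simulated raw EMG goes through the same spectral shaping.
    """
    if not 0 < low_hz < high_hz:
        raise DataError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= stream.fs / 2:
        raise DataError(f"high_hz={high_hz} must be below the Nyquist rate {stream.fs / 2}")
    sos = butter(4, (low_hz, high_hz), btype="bandpass", fs=stream.fs, output="sos")
    return replace(stream, signal=sosfiltfilt(sos, stream.signal))


def rms_envelope(stream: EMGStream, window_ms: float = RMS_WINDOW_MS) -> EMGEnvelope:
    """Sliding root-mean-square with a centered window.

    The window spans t − w/2 .. t + w/2 and is normalized by the number of
    samples actually inside it, so edges truncate instead of zero-padding.
    Output is sampled on the input time base.
    """
    half = int(round(window_ms / 2000.0 * stream.fs))
    if 2 * half + 1 < 2:
        raise DataError(f"RMS window of {window_ms} ms spans <2 samples at fs={stream.fs}")
    n = stream.n
    csum = np.concatenate([[0.0], np.cumsum(stream.signal**2)])
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, None)
    hi = np.clip(idx + half + 1, None, n)
    rms = np.sqrt((csum[hi] - csum[lo]) / (hi - lo))
    return EMGEnvelope(
        timestamps=stream.timestamps.copy(), rms=rms, muscle=stream.muscle, side=stream.side
    )


def compute_mvc_reference(mvc_trial: EMGStream, window_ms: float = RMS_WINDOW_MS) -> float:
    """Normalization reference: peak RMS over the maximum-effort trial."""
    if mvc_trial.timestamps[-1] - mvc_trial.timestamps[0] < 1.0:
        raise DataError("MVC trial shorter than 1 s cannot define a reliable reference")
    mvc_max = float(rms_envelope(bandpass_filter(mvc_trial), window_ms).rms.max())
    if mvc_max <= 0.0:
        raise DataError("all-zero MVC trial: invalid normalization reference")
    return mvc_max


def percent_mvc(envelope: EMGEnvelope, mvc_max: float) -> EMGEnvelope:
    """Express the envelope as a percentage of the MVC reference."""
    if not np.isfinite(mvc_max) or mvc_max <= 0:
        raise DataError(f"mvc_max must be a positive number, got {mvc_max}")
    return replace(envelope, pct_mvc=100.0 * envelope.rms / mvc_max)


def body_metrics(body: BodySpec) -> BodyMetrics:
    """BMI = weight / height² and the calf-to-limb length ratio."""
    return BodyMetrics(
        bmi=body.weight_kg / body.height_m**2,
        lower_limb_ratio=body.calf_length_cm / body.lower_limb_length_cm,
    )


def cycle_targets(
    envelope: EMGEnvelope,
    hs_times: np.ndarray,
    retained_cycles: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cycle activity targets from a %MVC envelope.

    Cycle i spans [HS(i), HS(i+1)); its targets are the mean and maximum
    %MVC over the samples inside.  ``retained_cycles`` restricts the output
    to the cycles whose strides survived the misstep filter, keeping target
    rows paired with feature rows.  Cycles falling outside the envelope's
    time range are dropped.
    """
    if envelope.pct_mvc is None:
        raise DataError("envelope must be %MVC-normalized first (see percent_mvc)")
    hs_times = np.atleast_1d(np.asarray(hs_times, dtype=float))
    t = envelope.timestamps
    rows = []
    for i in range(hs_times.size - 1):
        if retained_cycles is not None and i not in retained_cycles:
            continue
        sel = (t >= hs_times[i]) & (t < hs_times[i + 1])
        if not np.any(sel) or hs_times[i] < t[0] or hs_times[i + 1] > t[-1] + 1e-9:
            continue  # cycle outside the envelope's range
        seg = envelope.pct_mvc[sel]
        rows.append((i, float(seg.mean()), float(seg.max()), envelope.muscle))
    return pd.DataFrame(rows, columns=["cycle_index", "mvc_avg", "mvc_peak", "muscle"])


def emg_targets_for_session(
    walking: EMGStream,
    mvc_trial: EMGStream,
    hs_times: np.ndarray,
    retained_cycles: np.ndarray | None = None,
    window_ms: float = RMS_WINDOW_MS,
) -> pd.DataFrame:
    """Convenience chain: filter → RMS → %MVC → per-cycle aggregation."""
    mvc_max = compute_mvc_reference(mvc_trial, window_ms)
    env = percent_mvc(rms_envelope(bandpass_filter(walking), window_ms), mvc_max)
    return cycle_targets(env, hs_times, retained_cycles)
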