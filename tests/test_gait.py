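"""Event detection, ZUPT integration, distance/stride computation."""

import numpy as np
import pandas as pd
import pytest

from gaitmyo import quat
from gaitmyo.errors import ConfigError, DataError
from gaitmyo.gait import (
    DistanceTrace,
    GaitConfig,
    GaitEvents,
    detect_gait_events,
    extract_gait_features,
    segment_phases,
    stride_lengths,
    swing_peaks,
    to_global_frame,
    walking_distance,
    zupt_velocity,
)
from gaitmyo.io import G_TO_MS2, IMUStream, Session
from gaitmyo.orientation import OrientationTrace, estimate_orientation


def _static_stream(n=2000, fs=400.0):
    accel = np.tile([0, 0, 1.0], (n, 1))
    return IMUStream(np.arange(n) / fs, accel, np.zeros((n, 3)), fs=fs)


class TestEventDetection:
    def test_noiseless_simulation_events_within_25ms(self, noiseless_sim):
        session, truth = noiseless_sim
        ev = detect_gait_events(session.imu("ankle"))
        assert ev.n_hs == 10
        assert ev.all_to().size == 10
        assert ev.all_ms().size == 10
        np.testing.assert_allclose(ev.hs_times, truth.hs_times[1:], atol=0.025)
        np.testing.assert_allclose(ev.all_to(), truth.to_times, atol=0.025)
        np.testing.assert_allclose(ev.all_ms(), truth.ms_times, atol=0.025)

    def test_zero_gyro_gives_empty_events(self):
        ev = detect_gait_events(_static_stream())
        assert ev.is_empty and ev.n_cycles == 0

    def test_single_stride_yields_one_swing(self):
        from gaitmyo.simulate import GaitSimParams, simulate_session

        session, _ = simulate_session(
            GaitSimParams(n_strides=1, accel_noise_sd=0.0, gyro_noise_sd=0.0, seed=2)
        )
        ev = detect_gait_events(session.imu("ankle"))
        assert ev.n_hs == 1 and ev.all_ms().size == 1

    def test_bad_axis_is_config_error(self):
        with pytest.raises(ConfigError):
            GaitConfig(sagittal_axis=5)


class TestPhases:
    def test_direct_arithmetic(self):
        ev = GaitEvents(hs_times=[0.0, 1.0], to_times=[0.6], ms_times=[0.8])
        tbl = segment_phases(ev)
        assert tbl["stance_time"].tolist() == [pytest.approx(0.6)]
        assert tbl["swing_time"].tolist() == [pytest.approx(0.4)]

    def test_simulation_durations(self, noiseless_sim):
        session, _ = noiseless_sim
        tbl = segment_phases(detect_gait_events(session.imu("ankle")))
        # cadence 2 Hz, stance fraction 0.6 -> 0.3 s stance, 0.2 s swing
        np.testing.assert_allclose(tbl["stance_time"], 0.3, atol=0.03)
        np.testing.assert_allclose(tbl["swing_time"], 0.2, atol=0.03)

    def test_empty_events_empty_table(self):
        ev = detect_gait_events(_static_stream())
        assert segment_phases(ev).empty


class TestSwingPeaks:
    def test_constant_stream_peaks(self):
        s = _static_stream(n=800)
        ev = GaitEvents(hs_times=[0.5, 1.5], to_times=[1.1], ms_times=[1.3])
        pk = swing_peaks(s, ev)
        assert (pk["a_peak"] == 1.0).all()
        assert (pk["omega_peak"] == 0.0).all()

    def test_matches_bruteforce_on_random_stream(self, rng):
        n, fs = 2000, 400.0
        s = IMUStream(
            np.arange(n) / fs, rng.normal(0, 1, (n, 3)), rng.normal(0, 50, (n, 3)), fs=fs
        )
        ev = GaitEvents(
            hs_times=[1.0, 2.0, 3.0], to_times=[1.4, 2.4], ms_times=[1.7, 2.7],
            lead_to=0.4, lead_ms=0.7,
        )
        pk = swing_peaks(s, ev)
        t = s.timestamps
        for _, row in ev.swings().iterrows():
            sel = (t >= row["to"]) & (t <= row["hs_close"])
            expect_a = np.max([np.linalg.norm(a) for a in s.accel[sel]])
            got = pk.loc[pk["cycle_index"] == row["cycle_index"], "a_peak"].iloc[0]
            assert got == pytest.approx(expect_a, rel=1e-12)


class TestGlobalFrame:
    def test_gravity_cancellation(self):
        s = _static_stream(n=100)
        trace = OrientationTrace(
            s.timestamps, np.tile(quat.IDENTITY, (100, 1)), np.zeros(100)
        )
        a = to_global_frame(s, trace)
        np.testing.assert_allclose(a, 0.0, atol=1e-12)

    def test_yaw_rotation_closed_form(self):
        """90° yaw with local a=(1,0,1) G: the horizontal unit of
        acceleration lands on global y with magnitude 9.80665 m/s²."""
        n = 10
        q = quat.from_axis_angle([0, 0, 1], np.pi / 2)
        accel = np.tile([1.0, 0.0, 1.0], (n, 1))
        s = IMUStream(np.arange(n) / 400.0, accel, np.zeros((n, 3)), fs=400.0)
        trace = OrientationTrace(s.timestamps, np.tile(q, (n, 1)), np.zeros(n))
        a = to_global_frame(s, trace)
        np.testing.assert_allclose(a[0], [0.0, G_TO_MS2, 0.0], atol=1e-9)
        assert np.linalg.norm(a[0]) == pytest.approx(G_TO_MS2)

    def test_length_mismatch_raises(self):
        s = _static_stream(n=100)
        trace = OrientationTrace(s.timestamps[:50], np.tile(quat.IDENTITY, (50, 1)), np.zeros(50))
        with pytest.raises(DataError):
            to_global_frame(s, trace)


class TestZUPT:
    def test_all_zero_when_everything_inside_zero_intervals(self):
        a = np.ones((400, 3))
        ev = GaitEvents(hs_times=[10.0], to_times=[], ms_times=[])  # no swing at all
        vel = zupt_velocity(a, ev, fs=400.0)
        assert np.all(vel.v_norm == 0.0) and vel.zeroed_mask.all()

    def test_constant_acceleration_ramp(self):
        """1 m/s² along x over a 0.4 s live interval integrates to ~0.4 m/s."""
        fs = 400.0
        n = int(2.0 * fs)
        a = np.zeros((n, 3))
        a[:, 0] = 1.0
        ev = GaitEvents(hs_times=[0.2, 1.1], to_times=[0.8], ms_times=[1.0],
                        ff_times=[0.4, 1.2])
        vel = zupt_velocity(a, ev, fs=fs, zero_interval="stance-only")
        live = ~vel.zeroed_mask
        assert vel.v_norm[live].max() == pytest.approx(0.4, rel=0.02)
        assert np.all(vel.v_norm[vel.zeroed_mask] == 0.0)

    def test_matches_bruteforce_cumsum(self, rng):
        fs, n = 400.0, 1200
        a = rng.normal(0, 3, (n, 3))
        ev = GaitEvents(
            hs_times=[0.9, 1.9, 2.9], to_times=[1.5, 2.5], ms_times=[1.7, 2.7],
            ff_times=[1.0, 2.0, np.nan], lead_to=0.5, lead_ms=0.7,
        )
        for mode in ("stance-only", "as-printed"):
            vel = zupt_velocity(a, ev, fs=fs, zero_interval=mode)
            from gaitmyo.gait import _live_intervals

            t = np.arange(n) / fs
            vx = np.zeros(n)
            zeroed = np.ones(n, bool)
            for s0, s1 in _live_intervals(ev, mode, t[-1]):
                acc = 0.0
                for k in range(n):
                    if s0 < t[k] < s1:
                        acc += a[k, 0] / fs
                        vx[k] = acc
                        zeroed[k] = False
            np.testing.assert_allclose(vel.v_x, vx, rtol=1e-12, atol=1e-15)
            np.testing.assert_array_equal(vel.zeroed_mask, zeroed)


class TestDistanceAndStrides:
    def test_distance_staircase(self, noiseless_sim):
        session, _ = noiseless_sim
        stream = session.imu("ankle")
        ev = detect_gait_events(stream)
        trace = estimate_orientation(stream)
        a = to_global_frame(stream, trace)
        vel = zupt_velocity(a, ev, stream.fs, t0=stream.timestamps[0])
        dist = walking_distance(vel, stream.fs)
        # constant on zeroed spans, non-decreasing overall
        dX = np.diff(dist.X)
        assert np.all(dX >= 0)
        assert np.all(np.abs(dX[vel.zeroed_mask[1:]]) < 1e-9)

    def test_stride_length_direct_examples(self):
        t = np.linspace(0, 3, 301)
        X = np.interp(t, [0, 1, 2, 3], [0.8, 0.8, 2.0, 3.2])
        # X at heel strikes [1, 2, 3] = [0.8, 2.0, 3.2]
        d = DistanceTrace(t, X)
        df = stride_lengths(d, np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(df["l_stride"], [0.8, 1.2, 1.2])
        assert df["retained"].all()
        assert df["stride"].tolist() == [1, 2, 3]

    def test_misstep_filter_and_index_rule(self):
        t = np.linspace(0, 3, 301)
        X = np.interp(t, [0, 1, 2, 3], [1.2, 1.2, 1.4, 2.6])
        df = stride_lengths(DistanceTrace(t, X), np.array([1.0, 2.0, 3.0]))
        retained = df[df["retained"]]
        np.testing.assert_allclose(retained["l_stride"], [1.2, 1.2])
        # stride numbering skips the discarded misstep
        assert retained["stride"].tolist() == [1, 2]

    def test_single_short_stride_filtered(self):
        t = np.linspace(0, 1, 101)
        df = stride_lengths(DistanceTrace(t, np.full(101, 0.25)), np.array([0.5]))
        assert not df["retained"].any()

    def test_conservation_of_distance(self, rng):
        """Retained + discarded stride lengths sum to X at the last HS."""
        t = np.linspace(0, 10, 1001)
        X = np.cumsum(rng.uniform(0, 0.02, 1001))
        hs = np.sort(rng.uniform(0.5, 9.5, 8))
        df = stride_lengths(DistanceTrace(t, X), hs)
        x_last = X[np.searchsorted(t, hs[-1], side="right") - 1]
        assert df["l_stride"].sum() == pytest.approx(x_last, rel=1e-12)

    def test_filter_monotonicity(self, rng):
        t = np.linspace(0, 10, 1001)
        X = np.cumsum(rng.uniform(0, 0.02, 1001))
        hs = np.sort(rng.uniform(0.5, 9.5, 10))
        d = DistanceTrace(t, X)
        counts = [
            stride_lengths(d, hs, min_length_m=thr)["retained"].sum()
            for thr in [0.0, 0.1, 0.3, 0.5, 1.0]
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFullChain:
    def test_noiseless_ten_strides(self, noiseless_sim):
        session, _ = noiseless_sim
        feats = extract_gait_features(session)
        assert len(feats) == 10
        np.testing.assert_allclose(feats["l_stride"], 1.2, rtol=0.05)
        assert (feats["v_peak"] > 0).all()

    def test_static_session_yields_no_records(self):
        session = Session(imu_streams=[_static_stream()])
        assert extract_gait_features(session).empty

    def test_as_printed_zero_interval_halves_symmetric_strides(self, noiseless_sim):
        """The literal zero interval (heel strike through next mid-swing)
        suppresses the first half of every swing, so a symmetric swing
        profile yields roughly half the true stride length — the reason
        stance-only zeroing is the default."""
        session, _ = noiseless_sim
        feats = extract_gait_features(session, GaitConfig(zero_interval="as-printed"))
        assert len(feats) > 0
        assert feats["l_stride"].mean() == pytest.approx(0.5 * 1.2, rel=0.15)
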