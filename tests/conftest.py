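"""Shared fixtures: simulated sessions and feature tables.

Everything is generated at test time from the package's own simulator with
fixed seeds; expensive fixtures are session-scoped so the suite builds each
condition once.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitmyo.simulate import GaitSimParams, simulate_feature_dataset, simulate_session


@pytest.fixture(scope="session")
def noiseless_sim():
    """10 strides of 1.2 m at 2 Hz, zero sensor noise: the exact oracle."""
    params = GaitSimParams(
        n_strides=10, stride_length=1.2, cadence=2.0,
        accel_noise_sd=0.0, gyro_noise_sd=0.0, seed=11,
    )
    return simulate_session(params)


@pytest.fixture(scope="session")
def noisy_sim():
    """Same walk with the default sensor noise (accel 0.02 G, gyro 1 deg/s)."""
    params = GaitSimParams(n_strides=10, stride_length=1.2, cadence=2.0, seed=11)
    return simulate_session(params)


@pytest.fixture(scope="session")
def feature_df():
    """2000-cycle feature/target table with 5%-of-range target noise."""
    return simulate_feature_dataset(n_cycles=2000, noise_frac=0.05, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
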