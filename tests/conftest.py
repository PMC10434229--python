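"""Shared fixtures and builders for the test suite."""

import numpy as np
import pytest

from adtfnet.preprocessing import EpochedRecording
from adtfnet.synthetic import (
    ConnectivitySchedule,
    ScheduleEntry,
    SimulationConfig,
    simulate_tv_mvar,
)


def make_recording(data, fs=250.0, tmin=-0.2):
    return EpochedRecording(np.asarray(data, dtype=float), sampling_rate=fs, tmin=tmin)


@pytest.fixture(scope="session")
def coupled_2node():
    """2-node system with a constant 1 -> 2 coupling of 0.5 at lag 1."""
    config = SimulationConfig(n_nodes=2, n_epochs=100, osc_freqs=(10.0, 7.0), seed=42)
    schedule = ConnectivitySchedule(
        (ScheduleEntry(source=0, target=1, lag=1, coefficient=0.5, onset=-0.2, offset=1.0),)
    )
    data = simulate_tv_mvar(schedule, config, rng=np.random.default_rng(42))
    return config, schedule, data


@pytest.fixture(scope="session")
def step_2node():
    """2-node system where a21 steps from 0 to 0.5 at t = 0.5 s."""
    config = SimulationConfig(n_nodes=2, n_epochs=100, osc_freqs=(10.0, 7.0), seed=7)
    schedule = ConnectivitySchedule(
        (ScheduleEntry(source=0, target=1, lag=1, coefficient=0.5, onset=0.5, offset=1.0),)
    )
    data = simulate_tv_mvar(schedule, config, rng=np.random.default_rng(7))
    return config, schedule, data
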