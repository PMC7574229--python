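"""Shared fixtures: small deterministic herd simulations and derived tables."""

import numpy as np
import pytest

from envtrace import SimConfig, simulate
from envtrace import pipeline


@pytest.fixture(scope="session")
def sim_tiny():
    """2 cows, 2 hours: enough for stream-level round trips."""
    return simulate(SimConfig(seed=11, n_cows=2, n_sessions=1, session_hours=2))


@pytest.fixture(scope="session")
def sim_small():
    """4 cows, 3 hours: exercises group features and the hourly build."""
    return simulate(SimConfig(seed=13, n_cows=4, n_sessions=1, session_hours=3))


@pytest.fixture(scope="session")
def small_grids(sim_small):
    return pipeline.sim_gps_grids(sim_small)


@pytest.fixture(scope="session")
def small_windows(sim_small, small_grids):
    return pipeline.window_table_for_hours(
        sim_small, small_grids, range(sim_small.config.total_s // 3600))


@pytest.fixture(scope="session")
def small_records(sim_small, small_grids):
    return pipeline.hourly_records_from_sim(sim_small, grids=small_grids)


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
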