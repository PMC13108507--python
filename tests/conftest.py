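import numpy as np
import pytest
from hypothesis import settings

import syncmeta as sm
from syncmeta import presets

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def run_config():
    return sm.RunConfig(discard_initial=60.0, edge_trim=5, n_iterations=100, seed=11)


@pytest.fixture(scope="session")
def stationary_cohort():
    """24 sessions × 5 min, 20 parcels in 2 moderately coupled networks."""
    cfg = presets.stationary_cohort_config(seed=7)
    sessions = sm.simulate_kuramoto_sessions(cfg)
    assignment = sm.make_network_assignment(cfg.network_sizes, cfg.labels)
    return sm.validate_cohort(sessions, assignment)


@pytest.fixture(scope="session")
def stationary_cache(stationary_cohort, run_config):
    return sm.CohortCache(stationary_cohort, run_config)


@pytest.fixture(scope="session")
def stationary_plan(stationary_cohort, run_config):
    return sm.build_split_plan(
        stationary_cohort.session_ids, run_config.n_iterations, run_config.seed
    )


@pytest.fixture(scope="session")
def tiny_assignment():
    return sm.make_network_assignment([3, 2], ["A", "B"])


def make_tone_session(freq=0.05, tr=1.0, n=600, n_parcels=3, session_id="tone"):
    t = np.arange(n) * tr
    data = np.column_stack([np.cos(2 * np.pi * freq * t)] * n_parcels)
    ids = tuple(f"P{i:03d}" for i in range(n_parcels))
    return sm.SessionSeries(data=data, tr=tr, session_id=session_id, parcel_ids=ids)
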