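import numpy as np
import pytest
from hypothesis import settings

from abxdyn import (
    DiscoveryParams,
    SimulationConfig,
    compute_intervals,
    make_fixture,
    simulate_timelines,
)

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")

# the generative conditions every recovery test simulates from
STUDY_PARAMS = DiscoveryParams(k=30, n=1.5, t_lag=28, t0=1900)
STUDY_HALF_LIFE = 15.0
STUDY_HORIZON = 2020


@pytest.fixture
def fixture_table():
    return make_fixture()


@pytest.fixture
def fixture_intervals(fixture_table):
    return compute_intervals(fixture_table, observation_year=2020)


@pytest.fixture
def study_table():
    """One synthetic timeline drawn at the study conditions."""
    cfg = SimulationConfig(
        dparams=STUDY_PARAMS, half_life=STUDY_HALF_LIFE,
        horizon_year=STUDY_HORIZON, seed=1,
    )
    return simulate_timelines(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)
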