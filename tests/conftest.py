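import numpy as np
import pytest

from loopmem import io
from loopmem.behavior_sim import default_params, simulate_cohort
from loopmem.design import (
    DesignConfig,
    build_retrieval_schedule,
    generate_events,
)


@pytest.fixture(scope="session")
def design_config():
    return DesignConfig(seed=20240)


@pytest.fixture(scope="session")
def events(design_config):
    return generate_events(design_config)


@pytest.fixture(scope="session")
def events_frame(events):
    return io.events_to_frame(events)


@pytest.fixture(scope="session")
def retrieval_schedule(events, design_config):
    rng = np.random.default_rng(77)
    return build_retrieval_schedule(events, design_config, rng)


@pytest.fixture(scope="session")
def cohort_outcomes(retrieval_schedule, events_frame):
    """50 simulated subjects under the default generative parameters."""
    params = default_params(seed=4242)
    return simulate_cohort(params, retrieval_schedule, 50, events=events_frame)
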