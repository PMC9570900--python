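from datetime import datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noon():
    return datetime(2022, 6, 1, 12, 0)


@pytest.fixture(scope="session")
def short_run():
    """One simulated day at zero noise, shared across tests."""
    from hydrotwin.config import SimConfig
    from hydrotwin.simulate import closed_loop_run

    return closed_loop_run(SimConfig(duration_days=1))
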