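import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stopforest as sf

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def friedman_noisy():
    return sf.gen_friedman1(200, noise_sd=1.0, seed=7)


@pytest.fixture(scope="session")
def piecewise_clean():
    return sf.gen_piecewise(120, (0.3, 0.6), (0.0, 5.0, 10.0), 0.0, seed=3)


@pytest.fixture(scope="session")
def piecewise_noisy():
    return sf.gen_piecewise(200, (0.3, 0.6), (0.0, 5.0, 10.0), 1.0, seed=11)


@pytest.fixture(scope="session")
def oracle_suite():
    return sf.gen_oracle_suite(max_n=30, max_p=4, count=50, seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
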