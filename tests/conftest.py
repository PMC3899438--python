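import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import surveysim as ss

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_pop():
    return ss.make_fixture("toy3cluster")


@pytest.fixture(scope="session")
def two_strata_pop():
    return ss.make_fixture("two_strata")


@pytest.fixture(scope="session")
def equal_cluster_pop():
    return ss.make_fixture("single_stratum_equal")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
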