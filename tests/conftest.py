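import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import walkepi

settings.register_profile(
    "walkepi",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("walkepi")


@pytest.fixture(scope="session")
def kernel_constants():
    """Structure-factor constants from a moderate Monte-Carlo run."""
    c, c_err = walkepi.estimate_second_moment(10**6, np.random.default_rng(0))
    return walkepi.derive_constants(c, c_err, n_samples=10**6, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
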