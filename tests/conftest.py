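import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import epistab as ep

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def epitopes():
    """The six bundled candidate epitopes E1-E6."""
    return ep.bundled_epitope_fixture()


@pytest.fixture(scope="session")
def counts_mask():
    """Full-chain stability mask consistent with the reported counts."""
    return ep.reported_counts_mask()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240938)
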