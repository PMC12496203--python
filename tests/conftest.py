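import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def linked_bundle():
    """One linked simulation shared by PLSR/validation tests."""
    from synphen.simulate import simulate_linked_experiment
    return simulate_linked_experiment(seed=3)
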