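import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20200206)


@pytest.fixture
def constant_demography():
    from sccoalsim import Demography

    return Demography.constant(10_000)


@pytest.fixture
def small_tree(rng, constant_demography):
    from sccoalsim import simulate_coalescent_genealogy

    return simulate_coalescent_genealogy(8, constant_demography, rng)
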