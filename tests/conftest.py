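import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hopfbrain import generate_core_periphery_sc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Desk-scale study conditions: 40 regions, a 6-node rich-club core boosted
#: x3 in both link probability and weight, 8% peripheral density. Chosen to
#: emulate the sparse, long-tailed weighted connectomes the whole-brain
#: model runs on while keeping the coupling regime identifiable over g in
#: [0, 3].
FIXTURE_N = 40
FIXTURE_HUBS = 6
FIXTURE_FACTOR = 3.0
FIXTURE_DENSITY = 0.08
FIXTURE_SEED = 12


@pytest.fixture(scope="session")
def fixture_sc():
    """The 40-node core-periphery connectome used across the suite."""
    return generate_core_periphery_sc(
        FIXTURE_N, FIXTURE_HUBS, FIXTURE_FACTOR, FIXTURE_DENSITY, seed=FIXTURE_SEED
    )


@pytest.fixture(scope="session")
def small_sc():
    """A 10-node core-periphery connectome (2 designated hubs)."""
    return generate_core_periphery_sc(10, 2, 3.0, 0.5, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
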