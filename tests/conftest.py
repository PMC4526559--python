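import pytest

from dpmdx import prostate_presets, sample_scenarios

#: One fixed seed for every randomized suite in the tests.
SEED = 1234


@pytest.fixture(scope="session")
def presets():
    return prostate_presets()


@pytest.fixture(scope="session")
def random_scenarios():
    """1,000 reproducible random valid scenarios."""
    return sample_scenarios(1000, seed=SEED)


@pytest.fixture(scope="session")
def small_random_scenarios(random_scenarios):
    return random_scenarios[:200]
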