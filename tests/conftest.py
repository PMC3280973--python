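import numpy as np
import pytest

from ragdelscan import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale simulator configuration (locus shrunk 100x)."""
    return sd.SimulatorConfig(seed=7, scale_factor=0.01)


@pytest.fixture(scope="session")
def desk_locus(desk_config):
    return sd.simulate_locus(desk_config)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
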