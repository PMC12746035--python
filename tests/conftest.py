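import numpy as np
import pytest
from hypothesis import settings

import gdpoet as g

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def screen_fixture():
    return g.make_screen_fixture()


@pytest.fixture(scope="session")
def small_config():
    """A fast GP configuration for structural tests."""
    return g.EvolutionConfig(population_size=20, generations=25, rng_seed=0)


@pytest.fixture(scope="session")
def planted_library():
    """Zero-noise 74-peptide library generated by the default planted model."""
    from gdpoet.synthetic_data import GroundTruth, simulate_library

    return simulate_library(GroundTruth(rng_seed=7))


def random_peptide(rng: np.random.Generator, length: int = 12) -> str:
    return "".join(g.AMINO_ACIDS[i] for i in rng.integers(20, size=length))
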