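import numpy as np
import pytest

from mitohet import GeneAnnotation, synthetic_genome


@pytest.fixture(scope="session")
def annotation():
    return GeneAnnotation.default()


@pytest.fixture(scope="session")
def genome():
    """A deterministic synthetic full-length mitochondrial genome."""
    return synthetic_genome(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
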