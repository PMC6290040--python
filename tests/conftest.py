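import numpy as np
import pytest

from ordsem.model import build_population_model


@pytest.fixture(scope="session")
def population():
    """Correct-specification population model shared across tests."""
    return build_population_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20181205)
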