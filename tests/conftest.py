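import numpy as np
import pytest

from qsdar import SyntheticConfig, generate_library


@pytest.fixture(scope="session")
def small_library():
    """A small deterministic library shared across read-only tests."""
    return generate_library(SyntheticConfig(n_molecules=200, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
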