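import numpy as np
import pytest

from excitonci.fixtures import make_guanine_like_counting_fixture
from excitonci.oracle import ModelSystem, make_oracle, polar_toy_dimer


@pytest.fixture(scope="session")
def counting_fixture():
    """4 identical fragments x (1 GS + 7 singlets + 3 triplets)."""
    return make_guanine_like_counting_fixture()


@pytest.fixture(scope="session")
def small_model():
    """Random 2-fragment model (2 orbitals / 2 electrons each), seed 7."""
    return ModelSystem.random((2, 2), (2, 2), seed=7)


@pytest.fixture(scope="session")
def small_oracle(small_model):
    return make_oracle(small_model)


@pytest.fixture(scope="session")
def polar_dimer_model():
    return polar_toy_dimer()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
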