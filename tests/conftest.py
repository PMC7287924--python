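import numpy as np
import pytest

from enoskit import Model
from enoskit.synthetic import generate_truth


@pytest.fixture(scope="session")
def model():
    """One compiled model per session; its resting-state cache is shared."""
    return Model()


@pytest.fixture(scope="session")
def rest_state(model):
    return model.pre_equilibrate()


@pytest.fixture(scope="session")
def truth_datasets(model):
    """Noise-free synthetic training data at the default parameters."""
    return generate_truth(model=model)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240426)
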