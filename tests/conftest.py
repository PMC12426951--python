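import numpy as np
import pytest

from dredct import CLASS_NAMES, generate_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny balanced three-class dataset (8/class at side 96) for model tests."""
    return generate_arrays(8, side=96, seed=7)


@pytest.fixture(scope="session")
def class_names():
    return CLASS_NAMES
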