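import numpy as np
import pytest

from lgbmdf.synthdata import generate_dti


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic DTI dataset used across protocol tests."""
    return generate_dti(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
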