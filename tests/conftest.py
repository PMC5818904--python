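import numpy as np
import pytest

from entroloc import generate_fundus


@pytest.fixture(scope="session")
def fundus():
    """One default-parameter synthetic fundus with ground truth."""
    return generate_fundus(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
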