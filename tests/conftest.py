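import numpy as np
import pytest

from privatekt.datasets import make_synthetic_classification
from privatekt.ldp import PrivacyParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset():
    """100-sample, 10-class, well-separated Gaussian mixture."""
    return make_synthetic_classification(100, 10, 8, 3.0, seed=1)


@pytest.fixture
def binary_params():
    """epsilon = ln 3, K = 1, C = 2 => beta = 0.5 exactly."""
    return PrivacyParams(epsilon=np.log(3.0), k=1, n_classes=2)
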