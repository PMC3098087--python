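import numpy as np
import pytest

from imbsim.core import CLASS1, CLASS2, ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(rng, n1=5, n2=5, p=7, shift=0.0):
    """Small random two-class dataset; Class-2 rows optionally mean-shifted."""
    values = rng.standard_normal((n1 + n2, p))
    values[n1:] += shift
    labels = np.concatenate([np.full(n1, CLASS1), np.full(n2, CLASS2)])
    return ExpressionDataset(values, labels)


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)
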