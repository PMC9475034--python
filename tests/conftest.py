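import numpy as np
import pytest

from psnfuse.psn import PSN


def random_affinity(n, seed, low=0.05, high=1.0):
    """Random symmetric affinity with zero diagonal, entries in (0, 1]."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(low, high, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


@pytest.fixture
def k4_psn():
    a = np.ones((4, 4))
    np.fill_diagonal(a, 0.0)
    return PSN(affinity=a, patient_ids=np.arange(4))


@pytest.fixture
def p3_psn():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 1.0
    a[1, 2] = a[2, 1] = 1.0
    return PSN(affinity=a, patient_ids=np.arange(3))


@pytest.fixture
def star_psn():
    # hub node 0 with 4 leaves
    a = np.zeros((5, 5))
    a[0, 1:] = a[1:, 0] = 1.0
    return PSN(affinity=a, patient_ids=np.arange(5))
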