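import numpy as np
import pytest

from bmtme import Dimensions, Grm, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dims():
    return Dimensions(2, 3, 2, 2)


@pytest.fixture
def small_pheno(small_dims, rng):
    """Complete 2-env, 3-line, 2-rep, 2-trait table with distinct values."""
    d = small_dims
    y = rng.normal(10.0, 1.0, size=(d.I, d.J, d.K, d.L))
    return PhenotypeTable.from_arrays(y)


@pytest.fixture
def small_grm(small_dims):
    d = small_dims
    G = 0.6 * np.eye(d.J) + 0.4 * np.ones((d.J, d.J))
    return Grm(G, [f"L{j + 1}" for j in range(d.J)])
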