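import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hierarchical_small():
    """A small (m=200) hierarchical benchmark for cheap pipeline tests."""
    from qsne import HierarchicalSpec, hierarchical_gaussian

    data, labels = hierarchical_gaussian(HierarchicalSpec(m=200, seed=7))
    return data, labels


@pytest.fixture(scope="session")
def hierarchical_full():
    """The full 1000-sample nested-Gaussian benchmark (shared across tests)."""
    from qsne import HierarchicalSpec, hierarchical_gaussian

    data, labels = hierarchical_gaussian(HierarchicalSpec(seed=0))
    return data, labels
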