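import numpy as np
import pytest

from brierscoremf import SyntheticConfig, sample_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def toy_dataset():
    """Small exactly factorizable two-class dataset."""
    return sample_dataset(SyntheticConfig(seed=1, n=50, k=2, m=50))


@pytest.fixture(scope="session")
def multiclass_dataset():
    """Five-class dataset, still desk scale."""
    return sample_dataset(SyntheticConfig(seed=7, n=60, k=5, m=40))
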