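import numpy as np
import pandas as pd
import pytest

from dabarrier.synthetic import generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The seed-0 default synthetic dataset (n=1000) shared across tests."""
    df, meta = generate_dataset(1000, seed=0)
    return df, meta


@pytest.fixture(scope="session")
def small_dataset():
    """A quick n=300 dataset for tests that refit models repeatedly."""
    df, _ = generate_dataset(300, seed=11)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
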