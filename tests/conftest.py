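import numpy as np
import pytest

from borvm import load_printed_margins, sample_cohort


@pytest.fixture(scope="session")
def spec():
    return load_printed_margins()


@pytest.fixture(scope="session")
def exact_cohort(spec):
    return sample_cohort(spec, mode="exact", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian blobs in 2-D, 100 points per class."""
    rng = np.random.default_rng(7)
    X0 = rng.normal(0.0, 0.6, size=(100, 2))
    X1 = rng.normal(3.0, 0.6, size=(100, 2))
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(100), np.ones(100)].astype(int)
    return X, y
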