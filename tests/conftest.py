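import numpy as np
import pytest

from mpapnn.datasets import DatasetSpec, make_dataset
from mpapnn.pnn import LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_train():
    """Two far-separated one-dimensional classes of two points each."""
    return LabeledDataset(
        features=np.array([[0.0], [0.05], [1.0], [1.05]]),
        labels=np.array(["A", "A", "B", "B"]),
    )


@pytest.fixture
def blobs_2d():
    """Well-separated two-class Gaussian blobs (n=60, d=2)."""
    return make_dataset(DatasetSpec("blobs", n=60, d=2, separation=8.0, seed=7))


@pytest.fixture
def moderate_blobs():
    """Overlapping blobs where the optimizer has room to improve."""
    return make_dataset(
        DatasetSpec("moderate", n=80, d=3, separation=1.5, noise_rate=0.05, seed=11)
    )
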