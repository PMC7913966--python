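import numpy as np
import pytest

from shapevo import TimeSeriesDataset, make_motif_two_class


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """Six short series, two classes, deterministic values."""
    series = [
        [0.0, 1.0, 2.0, 3.0, 2.0, 1.0],
        [0.1, 1.1, 2.1, 3.1, 2.1, 1.1],
        [0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.5],
        [3.0, 2.0, 1.0, 0.0, 1.0, 2.0],
        [3.1, 2.1, 1.1, 0.1, 1.1, 2.1],
        [3.0, 2.0, 1.0, 0.0, 1.0, 2.0, 2.5],
    ]
    return TimeSeriesDataset(series, [0, 0, 0, 1, 1, 1])


@pytest.fixture
def motif_dataset():
    """Separable two-class motif data at zero noise (fast end-to-end runs)."""
    return make_motif_two_class(
        n_per_class=6, length=30, motif_length=8, noise=0.0, seed=7
    )
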