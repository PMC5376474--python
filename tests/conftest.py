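import numpy as np
import pytest

from histmerge import histogram_from_counts


@pytest.fixture
def four_level_hist():
    """Counts [2, 2, 1, 3] on grays 0-3, all other bins empty (N = 8)."""
    counts = np.zeros(256, dtype=np.int64)
    counts[:4] = [2, 2, 1, 3]
    return histogram_from_counts(counts)


@pytest.fixture
def random_hist_factory():
    """Seeded factory for random dense 256-bin histograms."""

    def make(seed: int, low: int = 0, high: int = 100):
        rng = np.random.default_rng(seed)
        counts = rng.integers(low, high, size=256)
        if counts.sum() == 0:
            counts[0] = 1
        return histogram_from_counts(counts)

    return make
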