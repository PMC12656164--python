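import numpy as np
import pytest

from supconhar import SyntheticSpec, fixture_batch, make_dataset
from supconhar.prep import concat_window_sets, make_windows


@pytest.fixture(scope="session")
def tiny_windows():
    """24 windows, 3 activities x 4 users, every cell covered."""
    return fixture_batch(24, 3, 4, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset: 4 users x 3 activities, windowed."""
    spec = SyntheticSpec(n_users=4, n_activities=3, n_channels=3,
                         duration_per_pair=4.0, seed=7)
    recs = make_dataset(spec)
    return concat_window_sets(
        [make_windows(r, n_classes=spec.n_activities) for r in recs])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
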