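import numpy as np
import pytest

from eegsync.partitioning import APConfig
from eegsync.synthetic import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_spec():
    """Desk-scale synthetic profile: 8 channels, 512 samples."""
    return SyntheticSpec(seed=42, n_windows_per_class=3).fast()


@pytest.fixture
def fast_ap():
    """AP settings capped for test runtime; clustering quality is unaffected
    for the synthetic windows used here."""
    return APConfig(max_points=96)
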