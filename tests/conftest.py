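import numpy as np
import pytest

from maaseg.synth import SyntheticSpec, generate_tile


@pytest.fixture(scope="session")
def small_tile():
    """One deterministic 112×112 noiseless tile with a single gland."""
    spec = SyntheticSpec(seed=7, width=112, height=112, n_glands=1,
                         radius_range=(25, 40))
    return generate_tile(spec)


@pytest.fixture(scope="session")
def medium_tile():
    """A 168×168 tile with two glands (multi-patch grid)."""
    spec = SyntheticSpec(seed=11, width=168, height=168, n_glands=2,
                         radius_range=(20, 40))
    return generate_tile(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
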