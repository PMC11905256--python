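import numpy as np
import pytest

from ssdaseg.segnet import NetworkConfig
from ssdaseg.synthetic import PhantomSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """Smallest legal network: two stages, one downsample, 4-wide transformer."""
    return NetworkConfig(n_stages=2, base_width=4, glf_d_head=4, glf_depth=1)


@pytest.fixture(scope="session")
def small_net_cfg():
    return NetworkConfig(n_stages=3, base_width=4, glf_d_head=8)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def tiny_dataset():
    """A miniature two-domain split for trainer contracts (8x8x8 grid)."""
    spec = PhantomSpec(grid_size=(16, 16, 8))
    return generate_dataset(spec, n_source=3, n_target=5, labeled_ratio=0.4,
                            seed=7, n_test=2)
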