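import numpy as np
import pytest

from tdcsfc.synthetic import SimConfig, make_atlas, make_subject_bold


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def atlas(default_config):
    return make_atlas(default_config)


@pytest.fixture(scope="session")
def quiet_config():
    """No spikes, for tests that need an artifact-free series."""
    return SimConfig(n_spikes=0, seed=5)


@pytest.fixture(scope="session")
def quiet_subject(quiet_config):
    atlas = make_atlas(quiet_config)
    return atlas, make_subject_bold(atlas, True, quiet_config, subject_seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
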