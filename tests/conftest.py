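import numpy as np
import pytest

from mimeseq import SimConfig, default_panel, draw_mirnome, make_reference


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_mirnas=8, depth=5000, seq_error=0.0,
                     tail_prob=0.2, star_prob=0.5)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return make_reference(small_config)


@pytest.fixture(scope="session")
def small_mirnome(small_config, small_reference):
    return draw_mirnome(small_config, small_reference)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
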