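import numpy as np
import pytest
from hypothesis import settings

from amygseg.arch import NetworkConfig, build_network

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


TINY_CONFIG = dict(
    layer_widths=(4, 4, 6),
    dilations_dilated=(1, 2, 1),
    dilations_standard=(1, 1, 1),
    n_classes=3,
    residual_blocks=((2, 3),),
)


@pytest.fixture
def tiny_config():
    return NetworkConfig(attention_mode="none", **TINY_CONFIG)


@pytest.fixture
def tiny_network(tiny_config):
    return build_network(tiny_config, seed=7)
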