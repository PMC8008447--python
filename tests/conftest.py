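import numpy as np
import pytest

from nanocorona import presets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spions_hsa_model():
    return presets.SPIONS_HSA_CORE_SHELL


@pytest.fixture
def hsa_ellipsoid_model():
    return presets.HSA_ELLIPSOID
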