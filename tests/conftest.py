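import numpy as np
import pytest

from spikeformer.spiking import SpikeActivationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spike_cfg():
    return SpikeActivationConfig(threshold=0.5, temp=5.0)
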