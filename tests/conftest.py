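import numpy as np
import pytest

from choiq.cho import ChannelParams, build_channel_bank
from choiq.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def bank64():
    return build_channel_bank(64)


@pytest.fixture(scope="session")
def default_params():
    return ChannelParams()


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(SyntheticConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
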