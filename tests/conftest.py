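import numpy as np
import pytest

from wfvit.model import ModelConfig
from wfvit.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def synth32_spec():
    return SyntheticSpec(image_size=32)


@pytest.fixture(scope="session")
def small_dataset(synth32_spec):
    """40 phantom images (10 per class) at 32x32, deterministic."""
    return generate_dataset(10, synth32_spec, seed=123)
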