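import numpy as np
import pytest

from nodulegan.phantom import PhantomConfig, generate_case


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free phantom for exact-value checks."""
    return PhantomConfig(noise_sigma=0.0, chest_wall=False, pleural_attachment_prob=0.0)


@pytest.fixture(scope="session")
def benign_case(default_config):
    return generate_case(default_config, "benign", seed=0)


@pytest.fixture(scope="session")
def malignant_case(default_config):
    return generate_case(default_config, "malignant", seed=1)
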