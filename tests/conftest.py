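import numpy as np
import pytest

from gatekin.synthetic import GeneratorConfig


@pytest.fixture
def config():
    """Default study-condition generator config with a fixed seed."""
    return GeneratorConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
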