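import numpy as np
import pytest

from wildfire_opioid import ModelParameters


@pytest.fixture
def params() -> ModelParameters:
    """Published defaults: 5.3% misuse, 6.6% anxiety, OR-dialect calibration."""
    return ModelParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160503)
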