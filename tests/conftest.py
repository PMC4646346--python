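import logging

import numpy as np
import pytest

from ventmech.mechanics import default_waveform
from ventmech.phantom import make_lung_phantom

logging.getLogger("ventmech").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom():
    """Standard small phantom shared across imaging tests."""
    return make_lung_phantom((48, 32, 8), seed=1)


@pytest.fixture(scope="session")
def waveform():
    """The default 7-tone design; phase optimization is the slow part,
    so design it once per session."""
    return default_waveform(seed=0)


@pytest.fixture(scope="session")
def waveform_zero_phase():
    return default_waveform(seed=0, optimize=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
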