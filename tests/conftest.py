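import numpy as np
import pytest

from lifesim import TimeGrid


@pytest.fixture
def grid():
    """1 s at the default 20 kHz rate."""
    return TimeGrid(sampling_rate=20_000.0, duration=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
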