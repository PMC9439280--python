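import numpy as np
import pytest

from fmfe.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_config():
    """A short, low-rate generator config that keeps unit tests quick while
    preserving the class structure (bands still below Nyquist at 2 kHz)."""
    return SyntheticConfig(sample_rate=2000, cycle_seconds=0.15)
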