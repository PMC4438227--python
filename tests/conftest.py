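import numpy as np
import pytest

from shape2behav.stimuli import build_stimulus_set


@pytest.fixture(scope="session")
def default_stimulus_set():
    """The default six-shape, luminance-equalized stimulus set (built once)."""
    return build_stimulus_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
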