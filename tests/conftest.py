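import warnings

import numpy as np
import pytest

# level-4 DWT on 75-sample feature windows provokes a pywt boundary-effect
# warning that is inherent to the chosen window/level pair
warnings.filterwarnings(
    "ignore", message="Level value of .* is too high", category=UserWarning
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rate():
    """Eye-tracker sampling rate used throughout (Hz)."""
    return 25.0
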