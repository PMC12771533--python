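import warnings

import numpy as np
import pytest

from paphantom.laws import ExtrapolationWarning


@pytest.fixture(autouse=True)
def _silence_extrapolation():
    """Domain flags are tested explicitly; keep other tests quiet."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
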