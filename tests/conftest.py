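import numpy as np
import pytest

from hrvent.series import Series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_series(rng):
    return Series(rng.standard_normal(512), units="a.u.", label="white_fixture")


@pytest.fixture
def short_gaussian(rng):
    return rng.standard_normal(128)
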