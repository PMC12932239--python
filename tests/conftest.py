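import numpy as np
import pytest

from needleplan.hough import build_direction_set


@pytest.fixture(scope="session")
def dirset2():
    return build_direction_set(2)


@pytest.fixture(scope="session")
def dirset6():
    return build_direction_set(6)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
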