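import numpy as np
import pytest

import featperc as fp


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def independent_dist():
    return fp.make_independent(0.5, 3.0)


@pytest.fixture(scope="session")
def positive_dist():
    return fp.make_positive(2.0)


@pytest.fixture(scope="session")
def negative_dist():
    return fp.make_negative(2.0)


@pytest.fixture(scope="session")
def f0_rule():
    return fp.OccupationRule.feature_upper_threshold(3.0)
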