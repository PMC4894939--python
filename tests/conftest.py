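import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def yule_rates():
    from agekin.rates import constant_rates
    return constant_rates(beta=1.0, mu=0.0)


@pytest.fixture
def exp_founder():
    from agekin.meanfield import InitialAgeDensity
    return InitialAgeDensity.exponential(rate=1.0)
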