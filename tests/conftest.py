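import numpy as np
import pytest

from fevalence import build_reference_schedule, sample_outcomes


@pytest.fixture(scope="session")
def reference_schedule():
    return build_reference_schedule()


@pytest.fixture(scope="session")
def reference_outcomes(reference_schedule):
    return sample_outcomes(reference_schedule, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20130613)
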