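import numpy as np
import pytest

from hexlearn import schedule as sched


@pytest.fixture(scope="session")
def default_schedule():
    return sched.build_schedule()


@pytest.fixture(scope="session")
def default_outcomes(default_schedule):
    return sched.sample_outcomes(default_schedule, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
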