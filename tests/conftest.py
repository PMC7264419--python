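from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

from freqnet import builtin_tasks

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tasks():
    return builtin_tasks()


@pytest.fixture(scope="session")
def mammography(tasks):
    return tasks["mammography"]


@pytest.fixture(scope="session")
def economics(tasks):
    return tasks["economics"]


@pytest.fixture(scope="session")
def mam_situation(mammography):
    return mammography.situation


@pytest.fixture(scope="session")
def eco_situation(economics):
    return economics.situation


@pytest.fixture
def frac():
    return Fraction
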