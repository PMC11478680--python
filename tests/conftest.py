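import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chlorospec import make_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny():
    """4 seedlings/treatment on a 5 nm grid: 76 leaves x 431 bands."""
    spectra, truth = make_fixture("tiny")
    return spectra, truth


@pytest.fixture(scope="session")
def tiny_spectra(tiny):
    return tiny[0]


@pytest.fixture(scope="session")
def study():
    """25 seedlings/treatment on the full 1 nm grid (~478 leaves)."""
    spectra, truth = make_fixture("study")
    return spectra, truth


@pytest.fixture(scope="session")
def study_spectra(study):
    return study[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
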