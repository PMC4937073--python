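import pytest

from nullprot.synthetic import SyntheticStudyConfig, make_synthetic_study


@pytest.fixture(scope="session")
def small_study():
    """A small noisy synthetic study shared across tests (n=300/arm)."""
    return make_synthetic_study(SyntheticStudyConfig(n=300, seed=11))


@pytest.fixture(scope="session")
def noiseless_study():
    """Noise-free study: binarized labels must equal the planted truth."""
    return make_synthetic_study(SyntheticStudyConfig(n=200, noise_sd=0.0, seed=5))


@pytest.fixture(scope="session")
def default_study():
    """The default study conditions (n=2000/arm, noise SD 0.1)."""
    return make_synthetic_study(SyntheticStudyConfig(seed=1))
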