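import numpy as np
import pytest

from exocea import CohortProfile, PSASpec, SyntheticSpec, generate_parameter_set


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def profile():
    return CohortProfile(start_age=65, sex="female", comorbidity="cvd")


@pytest.fixture(scope="session")
def bundle(spec, profile):
    return generate_parameter_set(spec, profile)


@pytest.fixture(scope="session")
def small_psa():
    return PSASpec(n_draws=100, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
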