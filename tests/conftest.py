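import numpy as np
import pytest
from hypothesis import settings

import aquajump as aj

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mean_subject() -> aj.SubjectProfile:
    """The cohort-mean subject (all spreads zero except resting rates, fixed)."""
    return aj.SubjectProfile(
        subject_id="MEAN",
        age=23.6,
        height=158.2,
        mass_land=53.1,
        rhr_land=70.0,
        rhr_water=62.0,
        water_depth=100.0,
    )


@pytest.fixture(scope="session")
def default_session(mean_subject):
    """One default three-phase session with stochastic defaults."""
    return aj.generate_session(mean_subject, seed=42)


@pytest.fixture(scope="session")
def noiseless_session(mean_subject):
    """Same session with every stochastic amplitude zeroed."""
    return aj.generate_session(mean_subject, config=aj.noiseless(), seed=42)


@pytest.fixture(scope="session")
def cohort12():
    """A 12-subject default cohort (the study-scale condition)."""
    return aj.generate_cohort(12, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
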