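import pytest

from casecausal import figure1_fixture, preset_dgp, sample_cohort
from casecausal.study import PRESETS


@pytest.fixture(scope="session")
def presets():
    """All preset specs, validated once per session."""
    return {name: preset_dgp(name) for name in PRESETS}


@pytest.fixture(scope="session")
def fig1():
    return figure1_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with events and survivors."""
    return sample_cohort(preset_dgp("confounded-binary"), 400, seed=7)


@pytest.fixture(scope="session")
def tv_cohort():
    """A cohort with time-varying exposure and covariates."""
    return sample_cohort(preset_dgp("tv-confounding"), 400, seed=8)
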