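import numpy as np
import pytest

from amylokin import (
    FIXTURE_RATES,
    RateConstants,
    ReactionConditions,
    make_reference_fixture,
)


@pytest.fixture(scope="session")
def reference_rates() -> RateConstants:
    """Reference parameter set: m0 = 2 uM, n_c = n_2 = 2,
    k_plus*k_n = 1e-4 uM^-2 h^-2, k_plus*k_2 = 1e3 uM^-3 h^-2."""
    k_plus = 1e4
    return RateConstants(k_n=1e-4 / k_plus, k_plus=k_plus, k_2=1e3 / k_plus)


@pytest.fixture(scope="session")
def unseeded() -> ReactionConditions:
    return ReactionConditions(m_total=2.0)


@pytest.fixture(scope="session")
def fixture_bundle():
    """The canonical synthetic campaign, generated once per session."""
    return make_reference_fixture()


@pytest.fixture(scope="session")
def fixture_rates() -> RateConstants:
    return FIXTURE_RATES


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
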