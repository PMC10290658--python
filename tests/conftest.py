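import numpy as np
import pytest

from hybridsheet import (
    fixture_catalytic_spec,
    make_active_site_fixture,
    make_beta_sheet_fixture,
    make_dissociation_trajectory,
)


@pytest.fixture(scope="session")
def spec():
    """CatalyticSpec matching the synthetic fixture naming scheme."""
    return fixture_catalytic_spec()


@pytest.fixture(scope="session")
def active_site():
    return make_active_site_fixture(2.0, 5.0, n_waters=3)


@pytest.fixture(scope="session")
def sheet():
    return make_beta_sheet_fixture(5)


@pytest.fixture(scope="session")
def planted():
    """Noise-free planted dissociation trajectory (exactly recoverable)."""
    return make_dissociation_trajectory(20, 10, seed=11, noise=0.0)


@pytest.fixture(scope="session")
def planted_noisy():
    return make_dissociation_trajectory(100, 50, seed=5, noise=0.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
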