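import numpy as np
import pytest

from squidsem import (
    ForcingSeries,
    SSTModel,
    default_fixture,
    default_initial_state,
    default_parameters,
    program_forcing,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def init(params):
    return default_initial_state(params)


@pytest.fixture(scope="session")
def fixture_bundle():
    """The default synthetic bundle: 1990-2025 forcing, 2001-2016 noisy
    observations from known parameters."""
    return default_fixture(seed=0, noise_cv=0.05)


@pytest.fixture(scope="session")
def noiseless_bundle():
    return default_fixture(seed=0, noise_cv=0.0)


@pytest.fixture(scope="session")
def mild_forcing(params):
    """Moderate-warming 1990-2025 forcing with catchability positive in
    every year (used for effort-inversion round trips)."""
    return program_forcing(params)


@pytest.fixture(scope="session")
def fifty_year_forcing(params):
    years = np.arange(1976, 2026)
    model = SSTModel(mean_anomaly=-0.4, trend=0.02, amplitude=0.5, period=6.0)
    return ForcingSeries.from_sst_model(model, years, params)
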