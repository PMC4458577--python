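import numpy as np
import pytest

from efatrans import (
    REFERENCE_CONVECTION_TIME,
    REFERENCE_PRIMARY,
    REFERENCE_RATE_CONSTANT,
    default_concentration_grid,
)


@pytest.fixture(scope="session")
def primary_params():
    """Published efavirenz estimates for the six-parameter advection-rate model."""
    return REFERENCE_PRIMARY


@pytest.fixture(scope="session")
def rate_constant_params():
    """Published efavirenz estimates for the five-parameter rate-constant model."""
    return REFERENCE_RATE_CONSTANT


@pytest.fixture(scope="session")
def convection_params():
    """Published single-patient Bateman convection-profile estimates."""
    return REFERENCE_CONVECTION_TIME


@pytest.fixture(scope="session")
def concentration_grid():
    return default_concentration_grid(200)


@pytest.fixture(scope="session")
def log_x_grid():
    """Log-spaced evaluation grid for derivative / monotonicity scans."""
    return np.geomspace(0.01, 60.0, 400)
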