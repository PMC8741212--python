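import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spherofit as sf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.disable(logging.WARNING)

# Limiting-structure means and mechanistic estimates for the three seeding
# densities of the WM983b-like reference analysis (used as numeric fixtures).
TABLE_MEANS = {
    2500: (340.0, 0.899, 0.719),
    5000: (353.0, 0.895, 0.716),
    10000: (356.0, 0.901, 0.742),
}
TABLE_THETA = {
    2500: (0.75, 149.0, 0.737),
    5000: (0.758, 156.0, 0.768),
    10000: (0.771, 145.0, 0.657),
}


@pytest.fixture(scope="session")
def gp_ref() -> sf.GreenspanParams:
    """Reference mechanistic parameters (2500-cell condition)."""
    return sf.GreenspanParams(0.75, 149.0, 0.737)


@pytest.fixture(scope="session")
def sigma_ref() -> np.ndarray:
    """Reference measurement covariance: sd 20 µm in R, 0.02 in phi, 0.1 in eta."""
    return np.diag([20.0**2, 0.02**2, 0.1**2])


@pytest.fixture(scope="session")
def steady_ref(gp_ref) -> sf.SteadyState:
    return sf.steady_state(gp_ref)


@pytest.fixture(scope="session")
def cohort_small():
    """One small synthetic cohort shared across tests (seeded, deterministic)."""
    from spherofit.cohort import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=11, n_per_condition=5))
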