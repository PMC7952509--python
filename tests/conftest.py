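import numpy as np
import pytest

from gmmresid import (
    GrowthModelSpec,
    GrowthParams,
    SimulationDesign,
    simulate,
)

# The study's fixed population values: factor variances, zero factor
# covariance, and heteroscedastic occasion residual variances.
PSI_DIAG = (0.25, 0.04)
THETA_DIAG = (0.15, 0.20, 0.20, 0.35)


@pytest.fixture(scope="session")
def linear_spec():
    return GrowthModelSpec(n_occasions=4)


@pytest.fixture(scope="session")
def study_params():
    return GrowthParams(
        eta_mean=np.array([0.5, 0.3]),
        psi=np.diag(PSI_DIAG),
        theta_diag=np.array(THETA_DIAG),
    )


@pytest.fixture(scope="session")
def single_class_data():
    """One homogeneous class at the study's fixed population values."""
    return simulate(SimulationDesign(k=1, n=10_000), seed=42)


@pytest.fixture(scope="session")
def two_class_separated():
    """Two well-separated classes (MD=5): label recovery should be easy."""
    return simulate(SimulationDesign(k=2, n=200, model=1, md=5.0), seed=7)
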