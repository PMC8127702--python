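import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gmatkit as gk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_params():
    """Six-trait default architecture without attrition or missingness."""
    return gk.default_params(attrition_rate=0.0, missing_rate_per_trait=0.0)


@pytest.fixture(scope="session")
def small_table(clean_params):
    """One population, 30 sires x 3 dams x 3 offspring, six traits."""
    design = gk.make_design(1, 30, 3, 3, 3, seed=0)
    return gk.simulate_phenotypes(design, clean_params)


def random_pd_matrix(rng: np.random.Generator, p: int) -> np.ndarray:
    """A well-conditioned random positive-definite matrix."""
    A = rng.standard_normal((p, p))
    return A @ A.T + p * np.eye(p)
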