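import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cytoscreen as cs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_cohort(X, y, names=None):
    """Small helper to build a CohortTable from raw arrays."""
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"v{j}" for j in range(X.shape[1])]
    ids = [f"p{i}" for i in range(X.shape[0])]
    return cs.CohortTable(patient_ids=ids, variables=list(names), X=X,
                          phenotype=np.asarray(y))


@pytest.fixture
def separable_cohort():
    """One variable perfectly separating the classes at 0, plus noise."""
    rng = np.random.default_rng(7)
    n = 60
    y = np.array([0] * 30 + [1] * 30)
    x0 = np.where(y == 0, -1.0, 1.0)
    noise = rng.standard_normal((n, 3))
    return make_cohort(np.column_stack([x0, noise]), y,
                       names=["sep", "n1", "n2", "n3"])


@pytest.fixture
def planted_cohort():
    """300 patients, 50 variables, five 1-SD planted effects of mixed sign."""
    spec = cs.SyntheticSpec(
        n_patients=300, n_vars=50,
        informative=[(0, 1.0), (10, -1.0), (20, 1.0), (30, -1.0), (40, 1.0)],
        latent_blocks=[list(range(i, i + 10)) for i in range(0, 50, 10)],
        rho=0.3, prevalence=0.48, seed=17)
    cohort, truth = cs.generate_cohort(spec)
    return cohort, truth
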