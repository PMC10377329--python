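import numpy as np
import pytest

from fconn.cohort import CohortSpec, LinearEdge, NonlinearEdge, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231046)


@pytest.fixture(scope="session")
def noise_cohort():
    """Edge-free cohort: pure band-limited noise, 10 ROIs, T=200."""
    spec = CohortSpec(n_per_group=2, labels=("CN",), n_rois=10,
                      n_timepoints=200, seed=1)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def linear_cohort():
    """One strong linear edge (0 -> 1, strength 5), T=500."""
    spec = CohortSpec(n_per_group=1, labels=("CN",), n_rois=4, n_timepoints=500,
                      linear_edges=(LinearEdge(0, 1, 5.0),), seed=1)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def quadratic_cohort():
    """One strong quadratic edge (0 -> 1, strength 5), T=500."""
    spec = CohortSpec(n_per_group=1, labels=("CN",), n_rois=4, n_timepoints=500,
                      nonlinear_edges=(NonlinearEdge(0, 1, "quadratic", 5.0),),
                      seed=1)
    return generate_cohort(spec)
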