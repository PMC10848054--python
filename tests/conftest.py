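import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_spec():
    """A desk-scale cohort: 42 parcels, 3x3x3 thalamic blocks, 3 per group."""
    from thalmod.cohort import default_cohort_spec

    spec = default_cohort_spec(seed=7)
    spec.n_per_group = {"HC": 3, "TLE-CN": 3, "TLE-CI": 3}
    spec.n_timepoints = 120
    spec.n_parcels = 42
    spec.partition = None
    spec.__post_init__()
    spec.thal_grid = (3, 3, 3)
    return spec


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    from thalmod.cohort import generate_cohort

    return generate_cohort(tiny_spec)
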