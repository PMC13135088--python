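import numpy as np
import pytest

from bctrisk.synthetic_data import (
    PhantomSpec,
    generate_phantom,
    CohortSpec,
    generate_cohort,
)
from bctrisk.trait_extraction import measure_all_traits


@pytest.fixture(scope="session")
def phantom():
    """Noise-free standard phantom (generated once per session)."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_traits(phantom):
    return measure_all_traits(
        phantom.hu, rois=phantom.rois, density_volume=phantom.density
    )


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic case-cohort table plus its ground truth."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """Larger cohort for selection/calibration power."""
    spec = CohortSpec(n_per_sex={"F": 24000, "M": 10000}, seed=7)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
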