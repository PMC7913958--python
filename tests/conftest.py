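import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bifocal.synthetic import SyntheticSpec, generate_slide_pair

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(width=1280, height=1280, positive_fraction_in_class=0.75, rng_seed=11)


@pytest.fixture(scope="session")
def small_slide_pair(small_spec):
    """One modest synthetic slide pair shared across the suite."""
    he, ihc, truth, transform = generate_slide_pair(small_spec)
    return {"he": he, "ihc": ihc, "truth": truth, "transform": transform}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
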