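import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gsiscan import CvSpec, default_pathway_spec, generate_two_class

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# fold-level fallback messages are expected on tiny folds; keep test output clean
logging.getLogger("gsiscan.cv").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pathway_data():
    """One draw of the default two-pathway synthetic matrix (134 x 23)."""
    return generate_two_class(default_pathway_spec(seed=5))


@pytest.fixture(scope="session")
def fast_cv_spec():
    """Single-run 10 x 10 CV configuration used to keep unit tests quick."""
    return CvSpec(C=1, seeds=tuple(range(1, 11)), tol=1e-6)
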