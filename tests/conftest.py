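import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def disjoint_catalog():
    from sparsesig.synthetic import make_signature_catalog

    return make_signature_catalog("disjoint")


@pytest.fixture(scope="session")
def cosmic_catalog():
    """Overlapping catalog with CA>AA-concentrated focal signature."""
    from sparsesig.synthetic import make_signature_catalog

    return make_signature_catalog("cosmic_like", np.random.default_rng(123))
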