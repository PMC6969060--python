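import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_signatures():
    """Two synthetic signatures with disjoint support (identifiable)."""
    from clonetrace.synthetic_data import synthetic_signature_matrix

    return synthetic_signature_matrix(n_signatures=2, seed=11, disjoint=True)


@pytest.fixture(scope="session")
def simulated_pair():
    """One realization of the canonical three-clone primary/met scenario."""
    from clonetrace.synthetic_data import simulate_patient, three_clone_two_lesion_config

    return simulate_patient(three_clone_two_lesion_config(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
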