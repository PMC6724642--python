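import pytest
from hypothesis import HealthCheck, settings

import timingnet as tn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    """(weights, saliency) reference parameter set."""
    return tn.reference_weights()


@pytest.fixture(scope="session")
def ref_weights(ref):
    return ref[0]

@pytest.fixture(scope="session")
def ref_saliency(ref):
    return ref[1]


@pytest.fixture(scope="session")
def peak_table():
    return tn.reference_peak_table()


@pytest.fixture(scope="session")
def tone_traj(ref_weights):
    return tn.simulate_network(tn.tone_protocol(), ref_weights)


@pytest.fixture(scope="session")
def flash_traj(ref_weights):
    return tn.simulate_network(tn.flash_protocol(), ref_weights)


@pytest.fixture(scope="session")
def compound_traj(ref):
    w, sal = ref
    return tn.simulate_network(tn.compound_protocol(), w, sal)


@pytest.fixture(scope="session")
def moderate_tone_target():
    """A tone-like target generated by the model itself (known weights)."""
    w = tn.NetworkWeights(w1=0.3, w2=-0.2, w3=2.0, w4=1.2, w5=3.0, w6=4.0)
    return tn.simulate_network(tn.tone_protocol(), w).x_out
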