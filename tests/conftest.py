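import pytest

from glucoloop import FITTED_MEAL, get_preset, simulate
from glucoloop.params import LumpedParams


@pytest.fixture(scope="session")
def healthy() -> LumpedParams:
    return get_preset("healthy_fitted")


@pytest.fixture(scope="session")
def diabetic() -> LumpedParams:
    return get_preset("diabetic_omega2")


@pytest.fixture(scope="session")
def meal():
    return FITTED_MEAL


@pytest.fixture(scope="session")
def diabetic_trajectory(diabetic, meal):
    """Uncontrolled diabetic meal response, shared across tests."""
    return simulate(diabetic, meal, horizon=10.0)


@pytest.fixture(scope="session")
def healthy_trajectory(healthy, meal):
    return simulate(healthy, meal, horizon=10.0)
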