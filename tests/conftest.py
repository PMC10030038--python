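import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from habitsim import ModelParameters, PlasticWeights, make_fixture

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Canonical parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def fast_params():
    """Short integration window for unit tests of invariants.

    150 ms is past the winner-take-all transient; statistical invariants
    checked with it do not depend on the full 600 ms default.
    """
    return ModelParameters(trial_duration=150.0)


@pytest.fixture(scope="session")
def symmetric_weights():
    return make_fixture("symmetric")


@pytest.fixture(scope="session")
def trained_weights():
    return make_fixture("trained-agent-weights", seed=1)
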