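import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from dystonia_reflex import run_battery, severity_sweep, get_preset


@pytest.fixture(scope="session")
def wrist_preset():
    return get_preset("wrist")


@pytest.fixture(scope="session")
def shoulder_preset():
    return get_preset("shoulder")


@pytest.fixture(scope="session")
def wrist_battery(wrist_preset):
    """The ten-condition battery for the wrist preset at default settings."""
    return run_battery(wrist_preset)


@pytest.fixture(scope="session")
def shoulder_battery(shoulder_preset):
    return run_battery(shoulder_preset)


@pytest.fixture(scope="session")
def wrist_reference(wrist_battery):
    return wrist_battery["reference"]


@pytest.fixture(scope="session")
def wrist_sweep(wrist_preset):
    """Imbalanced force-feedback sensitivity at increasing imbalance."""
    return severity_sweep(wrist_preset)


@pytest.fixture(scope="session")
def shoulder_sweep(shoulder_preset):
    return severity_sweep(shoulder_preset)
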