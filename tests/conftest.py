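import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vta_omission.session_model import ProtocolSpec, build_schedule

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hab_schedule():
    return build_schedule(ProtocolSpec.habituation(), seed=11)


@pytest.fixture(scope="session")
def ext_schedule():
    return build_schedule(ProtocolSpec.extinction(25), seed=12)


@pytest.fixture(scope="session")
def ext10_schedule():
    """A 10-trial extinction session (early extinction only)."""
    return build_schedule(ProtocolSpec.extinction(10), seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
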