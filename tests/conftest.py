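import pytest
from hypothesis import HealthCheck, settings

from ecotoxbench import Endpoint, load_pcc_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def daphnia_dataset():
    """Packaged 48-h daphnia validation table: (predictions, experiments)."""
    return load_pcc_fixture(Endpoint.DAPHNIA_48H)


@pytest.fixture(scope="session")
def fish_dataset():
    """Packaged 96-h fish validation table: (predictions, experiments)."""
    return load_pcc_fixture(Endpoint.FISH_96H)
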