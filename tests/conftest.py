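import pytest
from hypothesis import HealthCheck, settings

from dpcvalue import replication_config
from dpcvalue.fixtures import paper_catalog, paper_fee_schedule

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return paper_catalog()


@pytest.fixture(scope="session")
def fees():
    return paper_fee_schedule()


@pytest.fixture(scope="session")
def config():
    return replication_config()
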