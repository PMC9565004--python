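import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "dgene",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.filter_too_much],
)
settings.load_profile("dgene")

from dgene import expand, husbands_fixture  # noqa: E402


@pytest.fixture(scope="session")
def husbands():
    """The embedded husbands' dataset in compressed form (31 patterns, 6243)."""
    return husbands_fixture()


@pytest.fixture(scope="session")
def husbands_rows(husbands):
    """The husbands' dataset expanded back to 6,243 raw transactions."""
    return expand(husbands)
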