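import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    from carrierscreen import default_catalog

    return default_catalog()


@pytest.fixture(scope="session")
def test_layout(catalog):
    from carrierscreen import build_master_layout, build_test_layout

    return build_test_layout(build_master_layout(catalog))


@pytest.fixture(scope="session")
def master_layout(catalog):
    from carrierscreen import build_master_layout

    return build_master_layout(catalog)
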