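import pytest

from lungscreen import build_pool, default_parameter_fixture


@pytest.fixture(scope="session")
def fixture_params():
    return default_parameter_fixture()


@pytest.fixture(scope="session")
def small_pool(fixture_params):
    """Shared 3000-simulant pool; big enough for population-level assertions,
    small enough to keep the suite fast."""
    return build_pool(fixture_params, seed=7, n=3000)
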