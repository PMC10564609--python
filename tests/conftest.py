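import pytest

from sqlns_cea.parameters import default_uganda_config
from sqlns_cea.scenario_cea import SqlnsCeaModel
from sqlns_cea.synthetic_data import FixtureSpec, default_fixture


@pytest.fixture(scope="session")
def config():
    return default_uganda_config()


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def fixture(fixture_spec, config):
    """The calibrated default synthetic fixture (districts, items, cohorts)."""
    return default_fixture(fixture_spec, config)


@pytest.fixture(scope="session")
def base_results(config, fixture):
    districts, items, cohorts = fixture
    return SqlnsCeaModel(config, districts, items, cohorts).fit()
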