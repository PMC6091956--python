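import pytest

from ppp import GeneratorSpec, generate_projects, worked_fixture


@pytest.fixture
def fixture_projects():
    """Hand-built 5-project portfolio with known scores."""
    return worked_fixture()


@pytest.fixture(scope="session")
def small_portfolio():
    """A 60-project synthetic portfolio shared across statistical tests."""
    return generate_projects(GeneratorSpec(n_projects=60, seed=11))
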