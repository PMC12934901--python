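import pytest

from dmhkg.graph_builder import build_graph
from dmhkg.schema import SchemaConfig
from dmhkg.synthetic_corpus import default_spec, generate_corpus, regression_fixture


@pytest.fixture(scope="session")
def schema():
    return SchemaConfig()


@pytest.fixture(scope="session")
def fixture_result():
    return regression_fixture()


@pytest.fixture(scope="session")
def fixture_graph(fixture_result):
    return build_graph(fixture_result.corpus, fixture_result.synonym_map)


@pytest.fixture(scope="session")
def default_result():
    return generate_corpus(default_spec(seed=42))


@pytest.fixture(scope="session")
def default_graph(default_result):
    return build_graph(default_result.corpus, default_result.synonym_map)
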