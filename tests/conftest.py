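import pytest

from scb import build_schema
from scb.fixtures import FixtureConfig, generate, worked_example, figure6_example
from scb.pipeline import annotate_directory


@pytest.fixture(scope="session")
def schema():
    return build_schema()


@pytest.fixture(scope="session")
def worked_dir(tmp_path_factory):
    return worked_example(tmp_path_factory.mktemp("worked"))


@pytest.fixture(scope="session")
def worked_graph(worked_dir, schema):
    return annotate_directory(worked_dir, schema=schema)


@pytest.fixture(scope="session")
def fig6_dir(tmp_path_factory):
    return figure6_example(tmp_path_factory.mktemp("fig6"))


@pytest.fixture(scope="session")
def fig6_graph(fig6_dir, schema):
    return annotate_directory(fig6_dir, schema=schema)


@pytest.fixture(scope="session")
def fixture_config():
    return FixtureConfig(seed=11)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, fixture_config, schema):
    """Generated source directory + manifest + materialized graph."""
    out = tmp_path_factory.mktemp("generated")
    outdir, manifest = generate(fixture_config, out)
    graph = annotate_directory(outdir, schema=schema)
    return outdir, manifest, graph
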