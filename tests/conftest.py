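import pytest

from melipact import ThresholdPolicy, build_fixture, reclassify_table


@pytest.fixture(scope="session")
def default_policy():
    return ThresholdPolicy()


@pytest.fixture(scope="session")
def fixture_bundle():
    """Deterministic 609-record fixture table and its manifest."""
    return build_fixture(7)


@pytest.fixture(scope="session")
def fixture_table(fixture_bundle):
    return fixture_bundle[0]


@pytest.fixture(scope="session")
def fixture_manifest(fixture_bundle):
    return fixture_bundle[1]


@pytest.fixture(scope="session")
def reclassified_fixture(fixture_table):
    """Fixture table with final types set, plus the reclassification report."""
    return reclassify_table(fixture_table)
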