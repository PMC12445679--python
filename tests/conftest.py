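import pytest

from neuromcbs.fixtures import expected_scores, load_fixture
from neuromcbs.grading import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_comparative")


@pytest.fixture(scope="session")
def table1_expected():
    return expected_scores("table1_comparative")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_single_arm")


@pytest.fixture(scope="session")
def table2_expected():
    return expected_scores("table2_single_arm")
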