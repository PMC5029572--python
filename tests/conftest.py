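import pytest

from crypticsplice.fixtures import build_worked_example_fixtures
from crypticsplice.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def worked_fixtures():
    return build_worked_example_fixtures()


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (seed 1)."""
    return generate_dataset(SyntheticConfig(seed=1))
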