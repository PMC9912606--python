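import networkx as nx
import pytest
from hypothesis import settings

from fcig.synthetic import SyntheticConfig, generate_all

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def synthetic_run(default_config):
    """One fully generated synthetic study, shared across tests."""
    return generate_all(default_config)


@pytest.fixture()
def star5() -> nx.Graph:
    """Star with 4 leaves: centre has btw C(4,2)=6, BD sqrt(24)."""
    return nx.star_graph(4)


@pytest.fixture()
def path3() -> nx.Graph:
    return nx.path_graph(3)
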