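import networkx as nx
import pytest

from multimorbnet.synthetic_data import generate_study, paper_like_config


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared across tests (read-only)."""
    return generate_study(paper_like_config(seed=7, n_nodes=800))


@pytest.fixture()
def star_graph():
    G = nx.star_graph(5)  # node 0 is the hub
    return nx.relabel_nodes(G, {i: f"n{i}" for i in G})
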