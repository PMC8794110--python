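import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def fig1():
    """The canonical one-node decision neighbourhood (graph, state)."""
    from lcdago import fig1_fixture

    return fig1_fixture()


@pytest.fixture
def triangle():
    return nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def two_cliques():
    """Two 4-cliques joined by one bridge edge, with clique-specific terms."""
    g = nx.Graph()
    for group in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(group[i], group[j])
    g.add_edge("a1", "b1")
    terms = {
        n: frozenset({"t1", "t2"}) if n.startswith("a") else frozenset({"t3", "t4"})
        for n in g.nodes
    }
    return g, terms
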