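import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from boolhub.implication_net import ImplicationNetwork
from boolhub.recovery import recovery_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_net(edges, nodes=None, symmetric=False, layer_pair="mrna-mrna"):
    """Build an ImplicationNetwork from a plain edge list (both directions
    must be listed explicitly for symmetric graphs)."""
    g = nx.DiGraph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return ImplicationNetwork(graph=g, layer_pair=layer_pair, symmetric=symmetric)


def undirected_net(edges, nodes=None):
    """Symmetric network from undirected edge pairs."""
    both = [(u, v) for u, v in edges] + [(v, u) for u, v in edges]
    return make_net(both, nodes=nodes, symmetric=True)


@pytest.fixture(scope="session")
def recovery():
    """The planted-hub recovery benchmark at its reference seed."""
    return recovery_study(seed=1)
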