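import networkx as nx
import pytest

from bigramnet import from_edges


def net_from_nx(g) -> "object":
    """Wrap an unlabelled networkx graph as a BigramNetwork (v<i> labels)."""
    return from_edges(
        ((f"v{u}", f"v{v}") for u, v in g.edges),
        include_isolated=(f"v{v}" for v in g.nodes if g.degree(v) == 0),
    )


def random_net(n: int, p: float, seed: int):
    return net_from_nx(nx.gnp_random_graph(n, p, seed=seed))


@pytest.fixture
def k4():
    return from_edges([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")])


@pytest.fixture
def path3():
    return from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star4():
    """Hub with four leaves."""
    return from_edges([("H", "L1"), ("H", "L2"), ("H", "L3"), ("H", "L4")])


@pytest.fixture
def toy_core_hub():
    """Clique A-D plus hub F: degree 4 but attached to the core by one edge.

    F's other neighbours are leaves, so it peels at k = 2 despite its
    degree — the canonical peripheral-hub example.
    """
    return from_edges(
        [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D"),
         ("A", "F"), ("F", "L1"), ("F", "L2"), ("F", "L3")]
    )
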