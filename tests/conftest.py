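import networkx as nx
import pytest

import metabograph as mg


@pytest.fixture
def toy4_model():
    return mg.toy4()


@pytest.fixture
def toyhub_model():
    return mg.toyhub()


@pytest.fixture
def toycomp_model():
    return mg.toycomp()


@pytest.fixture
def toy4_network(toy4_model):
    """Compartmental build of the 4-metabolite irreversible cycle."""
    return mg.build_network(toy4_model, mg.NetworkSpec(compartmentalize=True))


@pytest.fixture
def star_network():
    """One metabolite feeding every reaction; each reaction otherwise terminal."""
    graph = nx.DiGraph()
    graph.add_node("hub", kind="metabolite", name="hub")
    for i in range(4):
        graph.add_node(f"r{i}", kind="reaction", name=f"r{i}")
        graph.add_node(f"leaf{i}", kind="metabolite", name=f"leaf{i}")
        graph.add_edge("hub", f"r{i}", role="reactant")
        graph.add_edge(f"r{i}", "hub", role="product")
        graph.add_edge(f"r{i}", f"leaf{i}", role="product")
        graph.add_edge(f"leaf{i}", f"r{i}", role="reactant")
    return mg.MetabolicNetwork(graph, mg.NetworkSpec(), provenance="star fixture")


@pytest.fixture
def tree_network():
    """Bipartite out-tree: no shared neighborhoods anywhere."""
    graph = nx.DiGraph()
    graph.add_node("m0", kind="metabolite", name="m0")
    for i in range(2):
        graph.add_node(f"t{i}", kind="reaction", name=f"t{i}")
        graph.add_edge("m0", f"t{i}", role="reactant")
        for j in range(2):
            leaf = f"m{i}{j}"
            graph.add_node(leaf, kind="metabolite", name=leaf)
            graph.add_edge(f"t{i}", leaf, role="product")
    return mg.MetabolicNetwork(graph, mg.NetworkSpec(), provenance="tree fixture")
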