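import networkx as nx
import pytest


@pytest.fixture
def star_graph():
    """4-leaf star: centre 'c', leaves l1..l4."""
    g = nx.Graph()
    g.add_edges_from([("c", f"l{i}") for i in range(1, 5)])
    return g


@pytest.fixture
def small_graph_suite():
    """Assorted graphs with ≤ 12 nodes for centrality oracle checks."""
    graphs = []
    g = nx.path_graph(5)
    graphs.append(nx.relabel_nodes(g, {i: f"p{i}" for i in g}))
    g = nx.cycle_graph(6)
    graphs.append(nx.relabel_nodes(g, {i: f"c{i}" for i in g}))
    g = nx.complete_graph(5)
    graphs.append(nx.relabel_nodes(g, {i: f"k{i}" for i in g}))
    star = nx.star_graph(5)
    graphs.append(nx.relabel_nodes(star, {i: f"s{i}" for i in star}))
    for seed in (1, 2, 3, 4):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        graphs.append(nx.relabel_nodes(g, {i: f"r{seed}_{i}" for i in g}))
    # disconnected: two triangles plus an isolated edge
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z"), ("u", "v")])
    graphs.append(g)
    return graphs
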