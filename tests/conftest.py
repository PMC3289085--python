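import pytest

import networkx as nx

from oiip import (
    WeightedNetwork,
    assign_edge_weights,
    parse_obo,
    propagate_annotations,
    read_edge_list,
)

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: g1
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: g2
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: g3
namespace: biological_process
is_a: GO:0000002 ! g1

[Term]
id: GO:0000005
name: g4
namespace: biological_process
is_a: GO:0000003 ! g2
"""

ROOT, G1, G2, G3, G4 = (f"GO:000000{i}" for i in range(1, 6))


@pytest.fixture(scope="session")
def toy_dag():
    """Five-term DAG: root; g1, g2 children; g3 under g1; g4 under g2."""
    return parse_obo(TOY_OBO)


@pytest.fixture(scope="session")
def toy_index(toy_dag):
    """P1, P2 directly on g3; P3 directly on g4 (so S_max = 3 at the root)."""
    direct = {"P1": {G3}, "P2": {G3}, "P3": {G4}}
    return propagate_annotations(direct, toy_dag)


def weighted_net_from_totals(edges):
    """Build a WeightedNetwork directly from {(u, v): total} (test scaffolding)."""
    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, s_sem=0.0, topo=0.0, total=float(w))
    vw = {n: sum(g.edges[n, m]["total"] for m in g[n]) for n in g.nodes}
    return WeightedNetwork(graph=g, vertex_weight=vw)


@pytest.fixture
def two_triangles_bridge():
    """Two unit-weight triangles joined by one bridge edge a3-b1."""
    edges = {}
    for a, b in [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                 ("b1", "b2"), ("b2", "b3"), ("b1", "b3"), ("a3", "b1")]:
        edges[(a, b)] = 1.0
    return weighted_net_from_totals(edges)


@pytest.fixture
def unit_k4():
    """K4 with every edge total = 1."""
    nodes = ["v1", "v2", "v3", "v4"]
    edges = {(u, v): 1.0 for i, u in enumerate(nodes) for v in nodes[i + 1:]}
    return weighted_net_from_totals(edges)


@pytest.fixture
def triangle_net():
    """Unweighted triangle run through the real weighting path (topo-only)."""
    return assign_edge_weights(read_edge_list("A B\nB C\nC A\n"))
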