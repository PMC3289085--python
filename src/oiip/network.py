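"""Weighted PPI graph construction: topology weights, edge/vertex weights, seed queue.

Each interaction edge (u, v) carries a reliability weight that is the sum of
the GO semantic similarity S_sem(u, v) and the shared-neighbor topology
weight |N(u) ∩ N(v)|.  A vertex weighs the sum of its incident edge weights;
the seed queue orders vertices by weight (then degree, then id) for cluster
seeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .ontology import AnnotationIndex, SimilarityScheme, log_ratio_scheme, semantic_similarity


class NetworkError(ValueError):
    pass


def read_edge_list(tsv_text: str) -> nx.Graph:
    """Parse a 2+-column whitespace/tab-delimited edge list into a simple graph.

    Lines starting with ``#`` or ``!`` are comments.  Self-loops are dropped
    and duplicate pairs (either orientation) collapsed, with counts logged on
    the returned graph (``graph.graph['n_self_loops']``, ``['n_duplicates']``).
    A third numeric column, if present, is ignored: weights are recomputed.
    """
    g = nx.Graph()
    n_self = n_dup = 0
    for line in tsv_text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "!")):
            continue
        parts = line.split()
        if len(parts) < 2:
            continue
        u, v = parts[0], parts[1]
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v)
    if g.number_of_edges() == 0:
        raise NetworkError("no usable edges in input")
    g.graph["n_self_loops"] = n_self
    g.graph["n_duplicates"] = n_dup
    return g


def topology_weight(u: str, v: str, graph: nx.Graph) -> int:
    """Number of neighbors shared by the endpoints of edge (u, v)."""
    if not graph.has_edge(u, v):
        raise NetworkError(f"no edge ({u}, {v}) in graph")
    shared = (set(graph[u]) & set(graph[v])) - {u, v}
    return len(shared)


@dataclass
class WeightedNetwork:
    """Undirected graph with per-edge (s_sem, topo, total) weights.

    ``total = s_sem + topo`` on every edge and each vertex weight is the sum
    of its incident totals, so Σ vertex_weight = 2 Σ total.
    """

    graph: nx.Graph
    vertex_weight: dict[str, float]

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    def degree(self, v: str) -> int:
        return self.graph.degree[v]

    def edge_total(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["total"]

    def to_tsv(self) -> str:
        """Weighted edge list with columns u, v, s_sem, topo, total (sorted)."""
        lines = ["#u\tv\ts_sem\ttopo\ttotal"]
        for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
            d = self.graph.edges[u, v]
            lines.append(f"{u}\t{v}\t{d['s_sem']:.6f}\t{d['topo']:.6f}\t{d['total']:.6f}")
        return "\n".join(lines) + "\n"


def assign_edge_weights(
    graph: nx.Graph,
    index: AnnotationIndex | None = None,
    scheme: SimilarityScheme = log_ratio_scheme,
    normalize_topo: bool = False,
) -> WeightedNetwork:
    """Attach s_sem, topo and total weights to every edge and weigh vertices.

    Unannotated proteins (or *index* = None) contribute s_sem = 0 on all
    their edges.  *normalize_topo* divides each topology weight by the
    graph-wide maximum shared-neighbor count (off by default: components are
    summed unscaled).
    """
    wg = graph.copy()
    topo_raw = {e: topology_weight(*e, graph) for e in wg.edges}
    max_topo = max(topo_raw.values()) if topo_raw else 0
    for (u, v), t in topo_raw.items():
        if index is not None and u in index.terms_by_protein and v in index.terms_by_protein:
            s = semantic_similarity(u, v, index, scheme)
        else:
            s = 0.0
        topo = t / max_topo if (normalize_topo and max_topo > 0) else float(t)
        wg.edges[u, v].update(s_sem=s, topo=topo, total=s + topo)
    vw = {
        n: sum(wg.edges[n, nbr]["total"] for nbr in wg[n])
        for n in wg.nodes
    }
    return WeightedNetwork(graph=wg, vertex_weight=vw)


def build_seed_queue(network: WeightedNetwork) -> list[str]:
    """Vertices sorted non-increasingly by weight, then degree, then id.

    The id tie-break makes the ordering (and every downstream clustering
    run) deterministic.
    """
    return sorted(
        network.graph.nodes,
        key=lambda v: (-network.vertex_weight[v], -network.graph.degree[v], v),
    )
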