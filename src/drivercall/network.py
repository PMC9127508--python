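"""Per-gene graph statistics on the filtered interaction network.

The network is undirected and unweighted: interaction scores gate edge
existence upstream but never act as weights. Closeness uses the
Wasserman-Faust correction so values remain comparable on disconnected
graphs; betweenness is exact (Brandes) with the standard pair
normalization.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import EdgeList


@dataclass
class NodeStats:
    gene: str
    degree: int
    closeness: float
    betweenness: float
    neighbors_by_hop: dict[int, set[str]] = field(default_factory=dict)


def _graph(edges: EdgeList | nx.Graph) -> nx.Graph:
    if isinstance(edges, nx.Graph):
        return edges
    g = nx.Graph()
    g.add_edges_from(edges.pairs())
    return g


def neighbors_within_hops(
    edges: EdgeList | nx.Graph, n: int
) -> dict[str, set[str]]:
    """BFS ball of radius ``n`` around each gene, excluding the gene itself."""
    if n < 1:
        raise ValueError(f"hop count must be >= 1, got {n}")
    g = _graph(edges)
    out: dict[str, set[str]] = {}
    for node in g.nodes:
        ball = nx.single_source_shortest_path_length(g, node, cutoff=n)
        out[node] = set(ball) - {node}
    return out


def node_centralities(
    edges: EdgeList | nx.Graph, max_hops: int = 1
) -> dict[str, NodeStats]:
    """Degree, closeness, betweenness and hop-neighborhoods for every gene."""
    g = _graph(edges)
    if g.number_of_nodes() == 0:
        return {}
    closeness = nx.closeness_centrality(g, wf_improved=True)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    hop_sets = {h: neighbors_within_hops(g, h) for h in range(1, max_hops + 1)}
    stats: dict[str, NodeStats] = {}
    for node in g.nodes:
        stats[node] = NodeStats(
            gene=node,
            degree=g.degree[node],
            closeness=closeness[node],
            betweenness=betweenness[node],
            neighbors_by_hop={h: hop_sets[h][node] for h in hop_sets},
        )
    return stats
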