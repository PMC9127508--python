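"""Brute-force reference implementations used by unit and acceptance tests.

These deliberately avoid networkx/sklearn shortcuts: distances come from a
plain BFS, shortest-path counts from a direct dynamic program, and metrics
from first-principles formulas, so agreement with the package is a real
cross-check rather than a tautology.
"""
from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distances(adjacency: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def oracle_degree(adjacency: dict[str, set[str]]) -> dict[str, int]:
    return {u: len(vs) for u, vs in adjacency.items()}


def oracle_hop_neighbors(adjacency: dict[str, set[str]], hops: int) -> dict[str, set[str]]:
    out = {}
    for u in adjacency:
        dist = bfs_distances(adjacency, u)
        out[u] = {v for v, d in dist.items() if 1 <= d <= hops}
    return out


def oracle_closeness(adjacency: dict[str, set[str]]) -> dict[str, float]:
    """Wasserman-Faust closeness: (r-1)/(n-1) * (r-1)/sum(d) over the
    reachable component of size r (including the node itself)."""
    n = len(adjacency)
    out = {}
    for u in adjacency:
        dist = bfs_distances(adjacency, u)
        total = sum(dist.values())
        r = len(dist)
        if total > 0 and n > 1:
            out[u] = (r - 1) / total * (r - 1) / (n - 1)
        else:
            out[u] = 0.0
    return out


def _path_counts(adjacency: dict[str, set[str]], source: str):
    """Number of shortest paths from ``source`` to every reachable node."""
    dist = bfs_distances(adjacency, source)
    sigma = {source: 1}
    for v in sorted(dist, key=dist.get):
        if v == source:
            continue
        sigma[v] = sum(sigma[u] for u in adjacency[v] if dist.get(u) == dist[v] - 1)
    return dist, sigma


def oracle_betweenness(adjacency: dict[str, set[str]]) -> dict[str, float]:
    """Pair-summation betweenness with the standard undirected normalization."""
    nodes = sorted(adjacency)
    n = len(nodes)
    dist = {}
    sigma = {}
    for u in nodes:
        dist[u], sigma[u] = _path_counts(adjacency, u)
    bt = dict.fromkeys(nodes, 0.0)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == d_st:
                    bt[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bt = {v: b * scale for v, b in bt.items()}
    return bt


def oracle_neigh_fc(gene, neighbors, logfc_map, tau):
    total, count = 0.0, 0
    for v in sorted(neighbors):
        if v in logfc_map and abs(logfc_map[v]) > tau:
            total += logfc_map[v]
            count += 1
    return (total, total / count) if count else (0.0, 0.0)


def oracle_neigh_cnv_fc(gene, neighbors, cnv_map, logfc_map, tau):
    total, count = 0.0, 0
    for v in sorted(neighbors):
        if cnv_map.get(v, 0) != 0 and v in logfc_map and abs(logfc_map[v]) > tau:
            total += logfc_map[v]
            count += 1
    return (total, total / count) if count else (0.0, 0.0)


def oracle_metrics(confusion: np.ndarray, classes: list[str]) -> dict:
    """Accuracy and per-class precision/recall/F1 from a confusion matrix."""
    cm = np.asarray(confusion, dtype=float)
    out = {"accuracy": float(np.trace(cm) / cm.sum()), "per_class": {}}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        support = cm[i].sum()
        predicted = cm[:, i].sum()
        precision = tp / predicted if predicted > 0 else float("nan")
        recall = tp / support if support > 0 else float("nan")
        if support == 0:
            f1 = float("nan")
        elif np.isnan(precision) or precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        out["per_class"][cls] = {"precision": precision, "recall": recall, "f1": f1}
    return out


def random_adjacency(rng: np.random.Generator, max_nodes: int = 15) -> dict[str, set[str]]:
    """A random simple undirected graph as an adjacency dict."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.1, 0.6))
    nodes = [f"n{i}" for i in range(n)]
    adjacency = {u: set() for u in nodes}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adjacency[nodes[i]].add(nodes[j])
                adjacency[nodes[j]].add(nodes[i])
    return adjacency
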