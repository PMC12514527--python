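"""Brute-force reference implementations used as independent oracles.

Everything here is written for clarity on tiny graphs (n <= ~8), by
exhaustive enumeration or fixed-point iteration, independent of the
library code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

TOL = 1e-12


def _adjacency(net: nx.Graph):
    nodes = list(net.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, d in net.edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = d["weight"]
    return nodes, w


def floyd_warshall_lengths(net: nx.Graph) -> tuple[list, np.ndarray]:
    """All-pairs shortest path lengths with edge length 1/weight."""
    nodes, w = _adjacency(net)
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[w > 0] = 1.0 / w[w > 0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return nodes, dist


def global_efficiency_brute(net: nx.Graph) -> float:
    nodes, dist = floyd_warshall_lengths(net)
    n = len(nodes)
    if n < 2:
        return 0.0
    total = sum(1.0 / dist[i, j]
                for i, j in itertools.combinations(range(n), 2)
                if np.isfinite(dist[i, j]) and dist[i, j] > 0)
    return total / (n * (n - 1) / 2)


def transitivity_brute(net: nx.Graph) -> float:
    nodes = list(net.nodes)
    triangles = 0
    for a, b, c in itertools.combinations(nodes, 3):
        if net.has_edge(a, b) and net.has_edge(b, c) and net.has_edge(a, c):
            triangles += 1
    triples = 0
    for v in nodes:
        k = net.degree(v)
        triples += k * (k - 1) // 2
    return 3.0 * triangles / triples if triples else 0.0


def density_brute(net: nx.Graph) -> float:
    n = net.number_of_nodes()
    return net.number_of_edges() / (n * (n - 1) / 2) if n > 1 else 0.0


def eigencentrality_brute(net: nx.Graph, iters: int = 20000) -> dict:
    """Shifted power iteration on the weighted adjacency, max-normalized.

    The diagonal shift keeps all eigenvalues positive so bipartite
    components cannot make the iteration oscillate, without changing
    eigenvectors or which eigenvalue is algebraically largest."""
    nodes, w = _adjacency(net)
    if w.sum() == 0:
        return {v: 0.0 for v in nodes}
    shift = 1.0 + w.sum(axis=1).max()
    shifted = w + shift * np.eye(len(nodes))
    vec = np.ones(len(nodes))
    for _ in range(iters):
        new = shifted @ vec
        norm = np.linalg.norm(new)
        if norm == 0:
            return {v: 0.0 for v in nodes}
        new = new / norm
        if np.linalg.norm(new - vec) < 1e-15:
            vec = new
            break
        vec = new
    vec = np.clip(vec, 0.0, None)
    vec = vec / vec.max()
    return {v: float(s) for v, s in zip(nodes, vec)}


def _all_simple_paths(net, s, t):
    nodes = list(net.nodes)
    others = [v for v in nodes if v not in (s, t)]
    for k in range(len(others) + 1):
        for mid in itertools.permutations(others, k):
            path = (s, *mid, t)
            if all(net.has_edge(a, b) for a, b in zip(path, path[1:])):
                yield path


def betweenness_brute(net: nx.Graph, normalized: bool = False) -> dict:
    """Fractional shortest-path counting by full path enumeration."""
    nodes = list(net.nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        for path in _all_simple_paths(net, s, t):
            length = sum(1.0 / net[a][b]["weight"]
                         for a, b in zip(path, path[1:]))
            paths.append((length, path))
        if not paths:
            continue
        best = min(p[0] for p in paths)
        shortest = [p for le, p in paths if le <= best * (1 + TOL) + TOL]
        sigma = len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                score[v] += 1.0 / sigma
    if normalized:
        n = len(nodes)
        scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
        score = {v: s * scale for v, s in score.items()}
    return score


def closeness_brute(net: nx.Graph) -> dict:
    """(reachable - 1) / sum of distances, within each component."""
    nodes, dist = floyd_warshall_lengths(net)
    out = {}
    for i, v in enumerate(nodes):
        reach = [j for j in range(len(nodes))
                 if j != i and np.isfinite(dist[i, j])]
        out[v] = (len(reach) / sum(dist[i, j] for j in reach)) if reach else 0.0
    return out


def modularity_brute(net: nx.Graph, membership: dict) -> float:
    """Weighted Newman-Girvan modularity evaluated from its definition."""
    nodes, w = _adjacency(net)
    two_m = w.sum()
    if two_m == 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if membership[u] == membership[v]:
                q += w[i, j] - k[i] * k[j] / two_m
    return q / two_m


def entropy_bits(counts) -> float:
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts if c > 0)


def random_weighted_graph(rng, n: int, p: float = 0.5) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(i, j, weight=float(rng.uniform(0.1, 1.0)))
    return g
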