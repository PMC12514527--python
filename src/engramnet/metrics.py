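"""Global and nodal network measures.

Edge weights are correlation coefficients, so a strong correlation means
a short functional distance: all shortest-path based measures (global
efficiency, betweenness, closeness) use edge length ``1/weight``.
Clustering is topological (binarized edges); eigenvector centrality uses
the weighted adjacency.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "global_efficiency",
    "clustering_coefficient",
    "edge_density",
    "eigencentrality_hub_scores",
    "path_centralities",
    "global_metrics",
    "node_metric_table",
    "normalize_to_baseline",
]


def with_lengths(net: nx.Graph) -> nx.Graph:
    """Copy of the graph with ``length = 1/weight`` on every edge."""
    g = net.copy()
    for u, v, d in g.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    return g


def global_efficiency(net: nx.Graph) -> float:
    """Mean inverse shortest-path length over all unordered node pairs.

    Disconnected pairs contribute 0.  A graph with fewer than 2 nodes has
    efficiency 0 by convention.
    """
    n = net.number_of_nodes()
    if n < 2:
        return 0.0
    g = with_lengths(net)
    inv_sum = 0.0
    for _, dists in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        inv_sum += sum(1.0 / d for d in dists.values() if d > 0)
    return inv_sum / (n * (n - 1))  # directed double-count cancels the 1/2


def clustering_coefficient(net: nx.Graph) -> float:
    """Global transitivity: 3 x triangles / connected triples, binarized."""
    return float(nx.transitivity(net))


def edge_density(net: nx.Graph) -> float:
    """Edges present over the maximum possible ``n(n-1)/2``."""
    n = net.number_of_nodes()
    if n < 2:
        return 0.0
    return net.number_of_edges() / (n * (n - 1) / 2)


def eigencentrality_hub_scores(net: nx.Graph) -> dict[str, float]:
    """Hub scores: the leading eigenvector of the weighted adjacency matrix.

    Entries are non-negative and scaled so the maximum is 1.  On a
    disconnected graph the dominant component carries the leading
    eigenpair; nodes outside it (including isolated nodes) score ~0.
    An edgeless graph yields all zeros with a warning.
    """
    nodes = list(net.nodes)
    if not nodes:
        raise ValueError("empty graph")
    if net.number_of_edges() == 0:
        warnings.warn("edgeless graph: all hub scores are 0", stacklevel=2)
        return {v: 0.0 for v in nodes}
    a = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    eigvals, eigvecs = np.linalg.eigh(a)
    vec = eigvecs[:, np.argmax(eigvals)]
    # Perron vector of the dominant component: fix the sign, clip the
    # numerically-zero negatives that eigh leaves on other components.
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    vec /= vec.max()
    return {v: float(s) for v, s in zip(nodes, vec)}


def path_centralities(net: nx.Graph,
                      normalized: bool = False) -> pd.DataFrame:
    """Betweenness and closeness on weighted shortest paths.

    Betweenness counts shortest paths through a node with fractional
    credit for ties (Brandes); ``normalized`` rescales by the pair count.
    Closeness of a node is ``(n_reachable - 1) / sum of distances``
    within its connected component.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    g = with_lengths(net)
    btw = nx.betweenness_centrality(g, weight="length", normalized=normalized)
    clo = nx.closeness_centrality(g, distance="length", wf_improved=False)
    return pd.DataFrame(
        {"betweenness": pd.Series(btw), "closeness": pd.Series(clo)}
    ).loc[list(net.nodes)].rename_axis("node")


def global_metrics(net: nx.Graph) -> dict[str, float]:
    """Global efficiency, clustering coefficient and edge density."""
    return {
        "global_efficiency": global_efficiency(net),
        "clustering_coefficient": clustering_coefficient(net),
        "edge_density": edge_density(net),
    }


def node_metric_table(net: nx.Graph) -> pd.DataFrame:
    """Per-node hub score, betweenness and closeness as one table."""
    table = path_centralities(net)
    hub = eigencentrality_hub_scores(net)
    table.insert(0, "hub_score", pd.Series(hub))
    return table


def normalize_to_baseline(values: pd.DataFrame,
                          baseline_bin: int = 0,
                          value_col: str = "value") -> pd.DataFrame:
    """Express each animal x bin value as % of its group's baseline mean.

    ``values`` is tidy with columns ``animal_id, group, bin`` and the
    value column; a ``normalized`` column is added so that the group mean
    at ``baseline_bin`` is exactly 100%.
    """
    required = {"animal_id", "group", "bin", value_col}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = values.copy()
    base = (out[out["bin"] == baseline_bin]
            .groupby("group")[value_col].mean())
    if (base == 0).any() or base.isna().any():
        bad = base[(base == 0) | base.isna()].index.tolist()
        raise ValueError(f"zero or undefined baseline mean for group(s) {bad}")
    out["normalized"] = out.apply(
        lambda r: 100.0 * r[value_col] / base[r["group"]], axis=1)
    return out
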