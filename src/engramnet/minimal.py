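"""Behavior-seeded minimal network extraction.

Regions whose hub scores correlate positively and significantly with
late extinction-learning performance seed a subnetwork comprising the
seeds and their immediate connections — the induced subgraph on seeds
plus neighbors, so neighbor-neighbor edges are kept.  Members are then
ranked by hub score, closeness and betweenness computed on the minimal
network itself, and its community structure is detected with Louvain.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .communities import CommunityPartition, detect_communities
from .metrics import node_metric_table

__all__ = ["MinimalNetwork", "select_behavior_hubs", "extract_minimal_network",
           "rank_minimal_centralities"]


@dataclass
class MinimalNetwork:
    graph: nx.Graph
    seed_nodes: set
    partition: CommunityPartition

    @property
    def members(self) -> list:
        return list(self.graph.nodes)


def select_behavior_hubs(correlations: pd.DataFrame,
                         alpha: float = 0.05) -> set:
    """Seed regions: positive, significant behavior-hub correlations.

    ``correlations`` is the per-node table from
    :func:`~engramnet.inference.behavior_hub_correlation` (columns ``r``
    and ``p``).  Negative correlates, however significant, are excluded.
    An empty selection is returned as-is (callers should treat it as a
    degraded outcome, not an error).
    """
    return set(correlations.index[(correlations["r"] > 0)
                                  & (correlations["p"] < alpha)])


def extract_minimal_network(source: nx.Graph, seeds: set,
                            louvain_seed: int = 0) -> MinimalNetwork:
    """Induced subgraph on the seeds and all their neighbors."""
    if not seeds:
        raise ValueError("empty seed set")
    missing = set(seeds) - set(source.nodes)
    if missing:
        raise ValueError(f"seeds not in source network: {sorted(map(str, missing))}")
    members = set(seeds)
    for s in seeds:
        members.update(source.neighbors(s))
    sub = source.subgraph(members).copy()
    sub.graph["provenance"] = "minimal"
    partition = detect_communities(sub, seed=louvain_seed) \
        if sub.number_of_edges() else CommunityPartition(
            {v: i for i, v in enumerate(sub.nodes)}, 0.0)
    return MinimalNetwork(graph=sub, seed_nodes=set(seeds), partition=partition)


def rank_minimal_centralities(mn: MinimalNetwork) -> dict[str, pd.DataFrame]:
    """Descending member rankings by hub score, closeness and betweenness.

    Centralities are computed on the minimal network itself, not
    inherited from the full network it was cut from.
    """
    if mn.graph.number_of_nodes() < 2:
        raise ValueError("minimal network needs at least 2 members to rank")
    table = node_metric_table(mn.graph)
    out = {}
    for metric in ("hub_score", "closeness", "betweenness"):
        ranked = table[[metric]].sort_values(metric, ascending=False)
        ranked["rank"] = range(1, len(ranked) + 1)
        out[metric] = ranked
    return out
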