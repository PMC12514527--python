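"""Community structure, connection diversity, and node roles.

Communities are detected with the Louvain algorithm on the weighted
modularity (resolution 1), seeded for reproducibility.  A node's
diversity score is the Shannon entropy (bits) of the community
membership distribution of its neighbors: 0 when all neighbors share a
community, higher when the node reaches many communities.  Crossing the
top-20% cuts of hub score and diversity yields the four-role taxonomy:
connector hubs, provincial hubs, non-hub connectors, peripheral nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CommunityPartition",
    "detect_communities",
    "diversity_scores",
    "classify_node_roles",
    "CONNECTOR_HUB",
    "PROVINCIAL_HUB",
    "NONHUB_CONNECTOR",
    "PERIPHERAL",
]

CONNECTOR_HUB = "ConnectorHub"
PROVINCIAL_HUB = "ProvincialHub"
NONHUB_CONNECTOR = "NonHubConnector"
PERIPHERAL = "Peripheral"


@dataclass
class CommunityPartition:
    """Node -> community label map plus the partition's modularity Q."""

    membership: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def as_sets(self) -> list[set]:
        groups: dict[int, set] = {}
        for node, c in self.membership.items():
            groups.setdefault(c, set()).add(node)
        return [groups[c] for c in sorted(groups)]


def detect_communities(net: nx.Graph, seed: int = 0,
                       resolution: float = 1.0) -> CommunityPartition:
    """Louvain communities of a weighted undirected network.

    Deterministic for a given seed.  An edgeless graph degenerates to
    one singleton community per node with Q = 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if net.number_of_edges() == 0:
        membership = {v: i for i, v in enumerate(net.nodes)}
        return CommunityPartition(membership=membership, modularity=0.0)
    comms = nx.community.louvain_communities(
        net, weight="weight", resolution=resolution, seed=seed)
    membership: dict[str, int] = {}
    for label, members in enumerate(sorted(comms, key=lambda s: sorted(map(str, s)))):
        for v in members:
            membership[v] = label
    q = nx.community.modularity(
        net, [set(c) for c in comms], weight="weight", resolution=resolution)
    return CommunityPartition(membership=membership, modularity=float(q))


def diversity_scores(net: nx.Graph,
                     partition: CommunityPartition) -> dict[str, float]:
    """Shannon entropy (bits) of each node's neighbor-community distribution.

    For node i with degree k, ``p_c`` is the fraction of its neighbors in
    community c and ``H_i = -sum_c p_c log2 p_c``.  Isolated nodes score 0.
    """
    missing = set(net.nodes) - set(partition.membership)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(map(str, missing))}")
    scores: dict[str, float] = {}
    for v in net.nodes:
        neighbors = list(net.neighbors(v))
        if not neighbors:
            scores[v] = 0.0
            continue
        counts: dict[int, int] = {}
        for u in neighbors:
            c = partition.membership[u]
            counts[c] = counts.get(c, 0) + 1
        k = len(neighbors)
        scores[v] = -sum((c / k) * math.log2(c / k) for c in counts.values())
    return scores


def _upper_quantile_threshold(values: np.ndarray, quantile: float) -> float:
    """Value of the ceil(quantile * n)-th largest entry (inclusive cut)."""
    k = max(1, math.ceil(quantile * len(values)))
    return float(np.sort(values)[::-1][k - 1])


def classify_node_roles(hub_scores: dict[str, float],
                        diversity: dict[str, float],
                        quantile: float = 0.20) -> pd.DataFrame:
    """Four-role taxonomy from the top-`quantile` cuts of hub and diversity.

    Nodes at or above the top-20% hub-score threshold are hubs; at or
    above the top-20% diversity threshold, connectors (ties at a
    threshold are included).  Hubs that are also connectors are
    ConnectorHubs, hubs that are not are ProvincialHubs; non-hubs are
    NonHubConnectors if high-diversity, else Peripheral.
    """
    if set(hub_scores) != set(diversity):
        raise ValueError("hub_scores and diversity must cover the same nodes")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    nodes = list(hub_scores)
    hub_vals = np.array([hub_scores[v] for v in nodes])
    div_vals = np.array([diversity[v] for v in nodes])
    hub_thr = _upper_quantile_threshold(hub_vals, quantile)
    div_thr = _upper_quantile_threshold(div_vals, quantile)
    is_hub = hub_vals >= hub_thr
    is_conn = div_vals >= div_thr
    roles = np.where(
        is_hub, np.where(is_conn, CONNECTOR_HUB, PROVINCIAL_HUB),
        np.where(is_conn, NONHUB_CONNECTOR, PERIPHERAL))
    return pd.DataFrame({
        "hub_score": hub_vals, "diversity_bits": div_vals,
        "is_hub": is_hub, "is_connector": is_conn, "role": roles,
    }, index=pd.Index(nodes, name="node"))
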