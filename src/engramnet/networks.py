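"""From ROI time series to thresholded functional networks.

Per animal and time bin, a Spearman correlation matrix over all region
pairs is computed, Bonferroni-adjusted over the pair family, and
thresholded: only positive correlations whose adjusted p-value falls
below alpha (default 0.001) become edges, weighted by the correlation
coefficient.  Group-level consensus networks retain edges significant
in at least a configurable fraction (default 75%) of the individual
networks, weighted by the mean coefficient over those occurrences.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "RoiTimeSeries",
    "CorrelationMatrix",
    "build_spearman_matrix",
    "threshold_to_network",
    "build_consensus_network",
]

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_FRACTION = 0.75


@dataclass
class RoiTimeSeries:
    """One animal's multi-region BOLD signal with time-bin boundaries.

    ``samples`` is regions x time (arbitrary units); ``bin_edges`` are
    sample indices delimiting the scan bins (T1 = baseline, T2..Tn =
    post-injection), so bin ``b`` covers ``samples[:, bin_edges[b]:bin_edges[b+1]]``.
    """

    animal_id: str
    group: str
    region_names: list[str]
    samples: np.ndarray
    bin_edges: list[int]
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D regions x time array")
        if len(self.region_names) != self.samples.shape[0]:
            raise ValueError("region_names length must match samples rows")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("region names must be unique")
        edges = list(self.bin_edges)
        if edges[0] != 0 or edges[-1] != self.samples.shape[1]:
            raise ValueError("bin_edges must start at 0 and end at n_samples")
        if any(b - a < 3 for a, b in zip(edges, edges[1:])):
            raise ValueError("each bin needs at least 3 samples")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_samples(self, bin_index: int) -> np.ndarray:
        if not 0 <= bin_index < self.n_bins:
            raise IndexError(f"bin_index {bin_index} out of range "
                             f"(animal {self.animal_id}, {self.n_bins} bins)")
        return self.samples[:, self.bin_edges[bin_index]:self.bin_edges[bin_index + 1]]


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho / p-value matrices for one animal and bin.

    ``p_adj`` is the Bonferroni adjustment over the ``m = C(n, 2)``
    unique region pairs: ``p_adj = min(1, m * p_raw)``.
    """

    region_names: list[str]
    rho: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    m: int
    animal_id: str = ""
    group: str = ""
    bin_index: int = -1

    def __post_init__(self) -> None:
        n = len(self.region_names)
        for name in ("rho", "p_raw", "p_adj"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if not np.allclose(mat, mat.T, equal_nan=True):
                raise ValueError(f"{name} must be symmetric")
            setattr(self, name, mat)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (tiny samples only)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
        if r >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def build_spearman_matrix(ts: RoiTimeSeries, bin_index: int,
                          p_method: str = "t") -> CorrelationMatrix:
    """Spearman correlation matrix of one animal's signals within one bin.

    Parameters
    ----------
    p_method
        ``"t"`` (default): the usual t-distribution approximation for the
        two-sided p-value.  ``"exact"``: full permutation enumeration,
        only sensible for bins of fewer than ~8 samples.

    Raises
    ------
    ValueError
        If any region has zero variance within the bin (the offending
        region is named) or the bin holds fewer than 3 samples.
    """
    data = ts.bin_samples(bin_index)
    n_regions, n_samples = data.shape
    if n_samples < 3:
        raise ValueError(f"bin {bin_index} has only {n_samples} samples (<3)")
    sds = data.std(axis=1)
    flat = [ts.region_names[i] for i in np.flatnonzero(sds == 0)]
    if flat:
        raise ValueError(
            f"zero-variance region(s) in bin {bin_index} of animal "
            f"{ts.animal_id}: {flat}")

    res = stats.spearmanr(data, axis=1)
    rho = np.atleast_2d(np.asarray(res.statistic, dtype=float))
    p_raw = np.atleast_2d(np.asarray(res.pvalue, dtype=float))
    if rho.shape == (1, 1):  # spearmanr collapses the 2-region case
        r = float(res.statistic)
        p = float(res.pvalue)
        rho = np.array([[1.0, r], [r, 1.0]])
        p_raw = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p_raw, 0.0)

    if p_method == "exact":
        if math.factorial(n_samples) > 500_000:
            raise ValueError("exact p-values are only supported for tiny bins")
        for i, j in itertools.combinations(range(n_regions), 2):
            p_raw[i, j] = p_raw[j, i] = _exact_spearman_p(data[i], data[j])
    elif p_method != "t":
        raise ValueError(f"unknown p_method: {p_method!r}")

    m = n_regions * (n_regions - 1) // 2
    p_adj = np.minimum(1.0, m * p_raw)
    np.fill_diagonal(p_adj, 0.0)
    return CorrelationMatrix(
        region_names=list(ts.region_names), rho=rho, p_raw=p_raw, p_adj=p_adj,
        m=m, animal_id=ts.animal_id, group=ts.group, bin_index=bin_index)


def threshold_to_network(cm: CorrelationMatrix,
                         alpha: float = DEFAULT_ALPHA) -> nx.Graph:
    """Threshold a correlation matrix into a weighted functional network.

    An edge (i, j) is present iff ``p_adj[i, j] < alpha`` and
    ``rho[i, j] > 0``; its weight is the correlation coefficient.  Every
    region stays in the node set, so isolated nodes are possible and node
    tables always have the full region count.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    g = nx.Graph()
    g.add_nodes_from(cm.region_names)
    n = len(cm.region_names)
    for i, j in itertools.combinations(range(n), 2):
        if cm.p_adj[i, j] < alpha and cm.rho[i, j] > 0:
            g.add_edge(cm.region_names[i], cm.region_names[j],
                       weight=float(cm.rho[i, j]))
    g.graph.update(provenance=f"{cm.animal_id}/bin{cm.bin_index}",
                   group=cm.group, bin_index=cm.bin_index, alpha=alpha)
    return g


def build_consensus_network(networks: list[nx.Graph],
                            cms: list[CorrelationMatrix] | None = None,
                            min_fraction: float = DEFAULT_MIN_FRACTION,
                            average: str = "significant") -> nx.Graph:
    """Group consensus of individual thresholded networks.

    An edge is retained iff it is present (significant and positive) in
    at least ``min_fraction`` of the individual networks; its weight is
    the mean coefficient over the networks where it was significant
    (``average="significant"``, the default) or over all animals
    (``average="all"``, which requires the matching correlation
    matrices).  Each retained edge records its ``retention_fraction``.
    """
    if len(networks) < 2:
        raise ValueError("consensus requires at least 2 individual networks")
    nodes = list(networks[0].nodes)
    for g in networks[1:]:
        if list(g.nodes) != nodes:
            raise ValueError("all networks must share an identical node set")
    if average == "all" and (cms is None or len(cms) != len(networks)):
        raise ValueError('average="all" requires one CorrelationMatrix per network')
    if average not in ("significant", "all"):
        raise ValueError(f"unknown averaging mode: {average!r}")

    consensus = nx.Graph()
    consensus.add_nodes_from(nodes)
    n_nets = len(networks)
    index = {r: i for i, r in enumerate(nodes)}
    for u, v in itertools.combinations(nodes, 2):
        present = [g for g in networks if g.has_edge(u, v)]
        fraction = len(present) / n_nets
        if fraction >= min_fraction and present:
            if average == "significant":
                weight = float(np.mean([g[u][v]["weight"] for g in present]))
            else:
                weight = float(np.mean(
                    [cm.rho[index[u], index[v]] for cm in cms]))
            consensus.add_edge(u, v, weight=weight, retention_fraction=fraction)
    consensus.graph.update(
        provenance="consensus", min_fraction=min_fraction,
        n_networks=n_nets, group=networks[0].graph.get("group", ""),
        bin_index=networks[0].graph.get("bin_index", -1))
    return consensus
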