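"""Resampling inference on network measures.

Three procedures:

* **BCa bootstrap group contrasts** — the difference of group means of a
  per-animal measure is resampled with replacement (default 1000 draws)
  and summarized with bias-corrected and accelerated confidence
  intervals at the 95/99/99.9% levels; an effect is significant at a
  level when that interval excludes zero.
* **Rewiring permutation test** — per-node differences in eigenvector
  centrality between two networks are referred to a null built by
  degree-preserving double-edge swaps of both networks (weights travel
  with their edges), with a two-sided proportion p-value.
* **Behavior-hub correlation** — per-region Pearson correlation between
  per-animal hub scores and late extinction-learning performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .metrics import eigencentrality_hub_scores

__all__ = [
    "BootstrapResult",
    "PermutationResult",
    "bootstrap_group_difference",
    "weighted_double_edge_swap",
    "rewire_permutation_test",
    "permutation_pvalues",
    "behavior_hub_correlation",
]

DEFAULT_LEVELS = (0.95, 0.99, 0.999)
_STARS = {0.95: "*", 0.99: "**", 0.999: "***"}


@dataclass
class BootstrapResult:
    metric: str
    observed: float
    n_boot: int
    intervals: dict[float, tuple[float, float]]
    significant: dict[float, bool]
    degenerate: bool = False

    @property
    def stars(self) -> str:
        """Highest conventional significance marker ('' if none)."""
        best = ""
        for level in sorted(self.significant):
            if self.significant[level]:
                best = _STARS.get(level, "*")
        return best


@dataclass
class PermutationResult:
    nodes: list[str]
    observed: dict[str, float]
    p_value: dict[str, float]
    n_perm: int
    null: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "observed_delta_hub": pd.Series(self.observed),
            "p_value": pd.Series(self.p_value),
        }).rename_axis("node")


def _bca_interval(boot: np.ndarray, observed: float, jack: np.ndarray,
                  level: float) -> tuple[float, float]:
    """BCa endpoints: bias correction from the bootstrap distribution,
    acceleration from jackknife skewness."""
    n_boot = len(boot)
    # Midpoint tie rule: half-weight draws equal to the observed value, so
    # a symmetric discrete bootstrap distribution gets z0 = 0 exactly.
    prop = (np.count_nonzero(boot < observed)
            + 0.5 * np.count_nonzero(boot == observed)) / n_boot
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = stats.norm.ppf(prop)
    resid = jack.mean() - jack
    denom = np.sum(resid**2) ** 1.5
    accel = np.sum(resid**3) / (6.0 * denom) if denom > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    out = []
    for za in (stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)):
        adj = stats.norm.cdf(z0 + (z0 + za) / (1.0 - accel * (z0 + za)))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]


def bootstrap_group_difference(group_a, group_b, n_boot: int = 1000,
                               levels=DEFAULT_LEVELS, seed=None,
                               metric: str = "") -> BootstrapResult:
    """BCa bootstrap of ``mean(group_a) - mean(group_b)``.

    ``seed`` may be an int or a numpy Generator.  With all-equal samples
    the interval collapses to a point and the result is flagged
    ``degenerate``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    observed = float(a.mean() - b.mean())

    idx_a = rng.integers(0, len(a), size=(n_boot, len(a)))
    idx_b = rng.integers(0, len(b), size=(n_boot, len(b)))
    boot = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)

    if np.ptp(boot) == 0.0:
        intervals = {lv: (observed, observed) for lv in levels}
        return BootstrapResult(metric=metric, observed=observed, n_boot=n_boot,
                               intervals=intervals,
                               significant={lv: observed != 0 for lv in levels},
                               degenerate=True)

    # Jackknife over the pooled leave-one-out replicates of the statistic.
    jack_a = (a.sum() - a) / (len(a) - 1) - b.mean()
    jack_b = a.mean() - (b.sum() - b) / (len(b) - 1)
    jack = np.concatenate([jack_a, jack_b])

    intervals = {lv: _bca_interval(boot, observed, jack, lv) for lv in levels}
    significant = {lv: not (lo <= 0.0 <= hi) for lv, (lo, hi) in intervals.items()}
    return BootstrapResult(metric=metric, observed=observed, n_boot=n_boot,
                           intervals=intervals, significant=significant)


@njit(cache=True)
def _swap_kernel(edge_u, edge_v, adj, n_swap, max_tries, seed):  # pragma: no cover
    np.random.seed(seed)
    m = edge_u.shape[0]
    swaps = 0
    tries = 0
    while swaps < n_swap and tries < max_tries:
        tries += 1
        i = np.random.randint(m)
        j = np.random.randint(m)
        if i == j:
            continue
        u, v = edge_u[i], edge_v[i]
        x, y = edge_u[j], edge_v[j]
        if np.random.random() < 0.5:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if adj[u, x] or adj[v, y]:
            continue
        adj[u, v] = adj[v, u] = False
        adj[x, y] = adj[y, x] = False
        adj[u, x] = adj[x, u] = True
        adj[v, y] = adj[y, v] = True
        edge_v[i] = x          # edge i becomes (u, x), keeps its weight
        edge_u[j] = v          # edge j becomes (v, y), keeps its weight
        edge_v[j] = y
        swaps += 1
    return swaps


def weighted_double_edge_swap(net: nx.Graph, n_swap: int, rng,
                              max_tries: int | None = None) -> nx.Graph:
    """Randomize a weighted graph by double-edge swaps, preserving degrees.

    A swap replaces edges (u, v) and (x, y) with (u, x) and (v, y) when
    this creates neither a self-loop nor a duplicate edge; each moved
    edge keeps its weight.  Returns a rewired copy after ``n_swap``
    successful swaps (or when ``max_tries`` candidate draws are
    exhausted; the default allows 100 tries per requested swap, which
    dense graphs with their high rejection rates do use).  Raises if the
    graph admits no swap at all.
    """
    if net.number_of_edges() < 2:
        raise ValueError("graph too sparse to rewire (fewer than 2 edges)")
    if max_tries is None:
        max_tries = 100 * n_swap
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    nodes = list(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    m = net.number_of_edges()
    edge_u = np.empty(m, dtype=np.int64)
    edge_v = np.empty(m, dtype=np.int64)
    weights = np.empty(m)
    adj = np.zeros((len(nodes), len(nodes)), dtype=np.bool_)
    for k, (u, v, d) in enumerate(net.edges(data=True)):
        iu, iv = index[u], index[v]
        edge_u[k], edge_v[k], weights[k] = iu, iv, d["weight"]
        adj[iu, iv] = adj[iv, iu] = True
    seed = int(rng.integers(0, 2**31 - 1))
    swaps = _swap_kernel(edge_u, edge_v, adj, n_swap, max_tries, seed)
    if swaps == 0:
        raise ValueError("graph admits no degree-preserving swap")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for k in range(m):
        g.add_edge(nodes[edge_u[k]], nodes[edge_v[k]], weight=float(weights[k]))
    g.graph.update(net.graph)
    return g


def permutation_pvalues(null: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Two-sided proportion p-values with +1 smoothing.

    ``p_j = (#{ |null_ij| >= |observed_j| } + 1) / (n_draws + 1)``, so p
    is never exactly 0 and lies in (0, 1].
    """
    null = np.atleast_2d(np.asarray(null, dtype=float))
    observed = np.asarray(observed, dtype=float)
    exceed = np.count_nonzero(np.abs(null) >= np.abs(observed), axis=0)
    return (exceed + 1.0) / (null.shape[0] + 1.0)


def _pack_edges(net: nx.Graph, nodes: list):
    """Edge arrays + boolean adjacency for the swap kernel."""
    index = {v: i for i, v in enumerate(nodes)}
    m = net.number_of_edges()
    if m < 2:
        raise ValueError("graph too sparse to rewire (fewer than 2 edges)")
    edge_u = np.empty(m, dtype=np.int64)
    edge_v = np.empty(m, dtype=np.int64)
    weights = np.empty(m)
    adj = np.zeros((len(nodes), len(nodes)), dtype=np.bool_)
    for k, (u, v, d) in enumerate(net.edges(data=True)):
        iu, iv = index[u], index[v]
        edge_u[k], edge_v[k], weights[k] = iu, iv, d["weight"]
        adj[iu, iv] = adj[iv, iu] = True
    return edge_u, edge_v, weights, adj


def _leading_eigvec_scores(w: np.ndarray) -> np.ndarray:
    """Max-normalized non-negative leading eigenvector of a symmetric matrix."""
    eigvals, eigvecs = np.linalg.eigh(w)
    vec = eigvecs[:, -1]
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    return vec / vec.max()


def rewire_permutation_test(net_a: nx.Graph, net_b: nx.Graph,
                            n_perm: int = 1000, seed=None,
                            swap_factor: int = 10) -> PermutationResult:
    """Permutation test on per-node hub-score differences via rewiring.

    The observed statistic is ``hub_score_A - hub_score_B`` per node
    (pass the reactivation network first for the usual sign convention).
    Each null draw rewires both networks independently with
    ``swap_factor * |E|`` degree-preserving swaps, recomputes hub
    scores, and records the null difference; the two-sided p-value is
    ``(#{|null| >= |observed|} + 1) / (n_perm + 1)``.
    """
    if set(net_a.nodes) != set(net_b.nodes):
        raise ValueError("networks must share an identical node set")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    nodes = list(net_a.nodes)
    hub_a = eigencentrality_hub_scores(net_a)
    hub_b = eigencentrality_hub_scores(net_b)
    observed = {v: hub_a[v] - hub_b[v] for v in nodes}

    # Null loop on flat arrays: copy edge arrays, swap in the compiled
    # kernel, score the leading eigenvector of the rebuilt adjacency.
    packed = [_pack_edges(net, nodes) for net in (net_a, net_b)]
    n = len(nodes)
    null = np.empty((n_perm, n))
    for k in range(n_perm):
        scores = []
        for edge_u, edge_v, weights, adj in packed:
            eu, ev, am = edge_u.copy(), edge_v.copy(), adj.copy()
            n_swap = swap_factor * len(eu)
            if _swap_kernel(eu, ev, am, n_swap, 100 * n_swap,
                            int(rng.integers(0, 2**31 - 1))) == 0:
                raise ValueError("graph admits no degree-preserving swap")
            w = np.zeros((n, n))
            w[eu, ev] = weights
            w[ev, eu] = weights
            scores.append(_leading_eigvec_scores(w))
        null[k] = scores[0] - scores[1]

    obs_vec = np.array([observed[v] for v in nodes])
    p = permutation_pvalues(null, obs_vec)
    return PermutationResult(nodes=nodes, observed=observed,
                             p_value={v: float(pv) for v, pv in zip(nodes, p)},
                             n_perm=n_perm, null=null)


def behavior_hub_correlation(hub_scores: pd.DataFrame,
                             performance: pd.Series) -> pd.DataFrame:
    """Per-region Pearson correlation of hub score with task performance.

    ``hub_scores`` is animals x regions (per-animal hub scores from each
    animal's own final-bin network); ``performance`` is late
    extinction-learning % correct indexed by the same animal ids, pooled
    across groups.  Returns a per-region table of r, two-sided p and n.
    """
    common = hub_scores.index.intersection(performance.index)
    if len(common) < 3:
        raise ValueError("need at least 3 matched animals")
    hs = hub_scores.loc[common]
    perf = performance.loc[common].astype(float)
    if perf.std() == 0:
        raise ValueError("behavior scores have zero variance")
    rows = {}
    for region in hs.columns:
        x = hs[region].astype(float)
        if x.std() == 0:
            raise ValueError(f"hub scores for region {region} have zero variance")
        r, p = stats.pearsonr(x, perf)
        rows[region] = {"r": float(r), "p": float(p), "n": len(common)}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("node")
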