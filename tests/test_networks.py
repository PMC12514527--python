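"""Spearman matrices, thresholding, and consensus construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from engramnet import (RoiTimeSeries, build_consensus_network,
                       build_spearman_matrix, threshold_to_network)
from engramnet.networks import CorrelationMatrix


def _ts(arrays, names=None, animal="a1", group="g"):
    data = np.asarray(arrays, dtype=float)
    names = names or [f"r{i}" for i in range(data.shape[0])]
    return RoiTimeSeries(animal_id=animal, group=group, region_names=names,
                         samples=data, bin_edges=[0, data.shape[1]])


class TestSpearman:
    def test_identical_series_give_rho_one(self):
        x = np.arange(10.0)
        cm = build_spearman_matrix(_ts([x, x + 5.0, np.sin(x) + x]), 0)
        assert cm.rho[0, 1] == pytest.approx(1.0)

    def test_antitone_map_gives_rho_minus_one(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 7.0])
        cm = build_spearman_matrix(_ts([x, -np.exp(x)]), 0)
        assert cm.rho[0, 1] == pytest.approx(-1.0)

    def test_matches_pearson_on_ranks(self):
        # x=(1..5), y=(2,1,4,3,5): ranks are the values themselves, so
        # rho equals the Pearson correlation of the rank vectors.
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        cm = build_spearman_matrix(_ts([x, y]), 0)
        assert cm.rho[0, 1] == pytest.approx(np.corrcoef(x, y)[0, 1],
                                             abs=1e-12)

    def test_agrees_with_rank_then_pearson_oracle(self, rng):
        from scipy.stats import rankdata
        data = rng.normal(size=(6, 40))  # continuous: no ties
        cm = build_spearman_matrix(_ts(data), 0)
        ranks = np.vstack([rankdata(row) for row in data])
        oracle = np.corrcoef(ranks)
        np.testing.assert_allclose(cm.rho, oracle, rtol=1e-10)

    def test_bonferroni_family_is_pair_count(self):
        data = np.random.default_rng(0).normal(size=(21, 30))
        cm = build_spearman_matrix(_ts(data), 0)
        assert cm.m == 210
        np.testing.assert_allclose(
            cm.p_adj[np.triu_indices(21, 1)],
            np.minimum(1.0, 210 * cm.p_raw[np.triu_indices(21, 1)]))

    def test_zero_variance_region_named_in_error(self):
        data = np.random.default_rng(0).normal(size=(3, 20))
        data[1] = 7.0
        with pytest.raises(ValueError, match="r1"):
            build_spearman_matrix(_ts(data), 0)

    def test_exact_permutation_p_close_to_t_for_strong_effect(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([1.2, 1.9, 3.4, 3.9, 5.1, 6.2])
        cm_t = build_spearman_matrix(_ts([x, y]), 0, p_method="t")
        cm_e = build_spearman_matrix(_ts([x, y]), 0, p_method="exact")
        # perfect rank agreement: exact two-sided p = 2/6! under the null
        assert cm_e.p_raw[0, 1] == pytest.approx(2 / 720)
        assert cm_t.rho[0, 1] == cm_e.rho[0, 1]


def _cm(rho, p_raw, names=None):
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    names = names or [f"r{i}" for i in range(n)]
    p_raw = np.asarray(p_raw, dtype=float)
    m = n * (n - 1) // 2
    p_adj = np.minimum(1.0, m * p_raw)
    np.fill_diagonal(p_adj, 0.0)
    return CorrelationMatrix(region_names=names, rho=rho, p_raw=p_raw,
                             p_adj=p_adj, m=m)


class TestThreshold:
    def test_all_nonsignificant_gives_isolated_nodes(self):
        n = 21
        cm = _cm(np.eye(n) * 0.5 + 0.5, np.full((n, n), 0.5))
        net = threshold_to_network(cm)
        assert net.number_of_nodes() == 21
        assert net.number_of_edges() == 0

    def test_negative_correlation_never_an_edge(self):
        rho = np.array([[1.0, -0.9], [-0.9, 1.0]])
        p = np.array([[0.0, 1e-9], [1e-9, 0.0]])
        net = threshold_to_network(_cm(rho, p))
        assert net.number_of_edges() == 0

    def test_adjustment_can_push_pair_over_alpha(self):
        # 21 regions -> m=210; p_raw=1e-5 -> p_adj=2.1e-3 > 0.001
        n = 21
        rho = np.full((n, n), 0.01)
        np.fill_diagonal(rho, 1.0)
        p = np.full((n, n), 0.9)
        rho[0, 1] = rho[1, 0] = 0.8
        p[0, 1] = p[1, 0] = 1e-5
        np.fill_diagonal(p, 0.0)
        cm = _cm(rho, p)
        assert cm.p_adj[0, 1] == pytest.approx(2.1e-3)
        assert threshold_to_network(cm, alpha=0.001).number_of_edges() == 0
        assert threshold_to_network(cm, alpha=0.01).number_of_edges() == 1

    @given(st.floats(1e-6, 0.5), st.floats(1e-6, 0.5),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_edge_set_monotone_in_alpha(self, a1, a2, seed):
        lo, hi = sorted((a1, a2))
        rng = np.random.default_rng(seed)
        n = 8
        rho = np.corrcoef(rng.normal(size=(n, 12)))
        p = rng.uniform(0, 0.05, size=(n, n))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 0.0)
        cm = _cm(rho, p)
        e_lo = set(threshold_to_network(cm, alpha=lo).edges)
        e_hi = set(threshold_to_network(cm, alpha=hi).edges)
        assert e_lo <= e_hi


def _net_from_edges(nodes, edges):
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


class TestConsensus:
    nodes = list("abcdefgh")

    def _networks(self, edge_weights):
        """8 individual networks; edge (a,b) present with given weights."""
        nets = []
        for k in range(8):
            edges = [("c", "d", 0.9)]  # an always-present edge
            if k < len(edge_weights):
                edges.append(("a", "b", edge_weights[k]))
            nets.append(_net_from_edges(self.nodes, edges))
        return nets

    def test_exact_75_percent_is_retained_and_below_dropped(self):
        cons6 = build_consensus_network(self._networks([0.5] * 6),
                                        min_fraction=0.75)
        assert cons6.has_edge("a", "b")
        assert cons6["a"]["b"]["retention_fraction"] == pytest.approx(0.75)
        cons5 = build_consensus_network(self._networks([0.5] * 5),
                                        min_fraction=0.75)
        assert not cons5.has_edge("a", "b")
        cons0 = build_consensus_network(self._networks([]))
        assert not cons0.has_edge("a", "b")

    def test_weight_is_mean_over_significant_occurrences(self):
        weights = [0.5, 0.6, 0.7, 0.8, 0.6, 0.4]
        cons = build_consensus_network(self._networks(weights))
        assert cons["a"]["b"]["weight"] == pytest.approx(np.mean(weights))

    def test_edge_set_shrinks_as_min_fraction_rises(self):
        nets = self._networks([0.5] * 6)
        for lo, hi in itertools.pairwise([0.5, 0.75, 0.9, 1.0]):
            e_hi = set(build_consensus_network(nets, min_fraction=hi).edges)
            e_lo = set(build_consensus_network(nets, min_fraction=lo).edges)
            assert e_hi <= e_lo

    def test_mismatched_node_sets_rejected(self):
        nets = [_net_from_edges(list("abc"), [("a", "b", 0.5)]),
                _net_from_edges(list("abd"), [("a", "b", 0.5)])]
        with pytest.raises(ValueError, match="identical node set"):
            build_consensus_network(nets)
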