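"""BCa bootstrap, rewiring permutation test, behavior correlations."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from engramnet import (behavior_hub_correlation, bootstrap_group_difference,
                       generate_toy_graph, permutation_pvalues,
                       rewire_permutation_test, weighted_double_edge_swap)


class TestBootstrap:
    def test_identical_groups_cover_zero(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        res = bootstrap_group_difference(vals, vals, n_boot=500, seed=0)
        assert res.observed == 0.0
        for lo, hi in res.intervals.values():
            assert lo <= 0.0 <= hi
        assert res.stars == ""

    def test_intervals_are_nested(self, rng):
        a = rng.normal(5, 1, size=8)
        b = rng.normal(3, 1, size=8)
        res = bootstrap_group_difference(a, b, n_boot=1000, seed=1)
        l95, h95 = res.intervals[0.95]
        l99, h99 = res.intervals[0.99]
        l999, h999 = res.intervals[0.999]
        assert l999 <= l99 <= l95 <= h95 <= h99 <= h999

    def test_clear_shift_detected_in_most_replicates(self):
        """A +10 shift with unit noise at n=8 excludes 0 from the 95% CI
        in at least 95% of replicate datasets."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            b = rng.normal(0, 1, size=8)
            a = b + 10 + rng.normal(0, 0.5, size=8)
            res = bootstrap_group_difference(a, b, n_boot=500, seed=rng)
            hits += res.significant[0.95]
        assert hits >= 95

    def test_star_rule(self, rng):
        a = rng.normal(20, 0.5, size=8)
        b = rng.normal(0, 0.5, size=8)
        res = bootstrap_group_difference(a, b, n_boot=1000, seed=2)
        assert res.significant[0.95]
        assert res.stars == "***"

    def test_degenerate_samples_flagged(self):
        res = bootstrap_group_difference([3.0] * 4, [3.0] * 4, n_boot=100,
                                         seed=0)
        assert res.degenerate
        assert res.intervals[0.95] == (0.0, 0.0)

    def test_reduces_to_percentile_when_symmetric(self):
        """With a symmetric bootstrap distribution (z0 ~ 0) and symmetric
        samples (a ~ 0), BCa endpoints approach plain percentiles."""
        a = np.array([-3.0, -1.0, 1.0, 3.0]) + 10
        b = np.array([-3.0, -1.0, 1.0, 3.0])
        rng = np.random.default_rng(7)
        idx_a = rng.integers(0, 4, size=(4000, 4))
        idx_b = rng.integers(0, 4, size=(4000, 4))
        boot = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
        res = bootstrap_group_difference(a, b, n_boot=4000, seed=7)
        lo, hi = res.intervals[0.95]
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=0.15)
        assert hi == pytest.approx(phi, abs=0.15)

    def test_matches_scipy_bca_oracle(self):
        """Endpoints agree with scipy's independent BCa implementation."""
        rng = np.random.default_rng(3)
        a = rng.normal(2, 1, size=10)
        b = rng.normal(0, 1, size=10)
        res = bootstrap_group_difference(a, b, n_boot=9999, seed=3)
        sci = stats.bootstrap(
            (a, b), lambda x, y, axis=-1: np.mean(x, axis=axis)
            - np.mean(y, axis=axis),
            n_resamples=9999, confidence_level=0.95, method="BCa",
            random_state=np.random.default_rng(3))
        lo, hi = res.intervals[0.95]
        assert lo == pytest.approx(sci.confidence_interval.low, abs=0.1)
        assert hi == pytest.approx(sci.confidence_interval.high, abs=0.1)


class TestRewiring:
    def test_swap_preserves_degrees_and_weight_multiset(self, rng):
        g = oracles.random_weighted_graph(rng, 10, 0.4)
        rewired = weighted_double_edge_swap(g, 10 * g.number_of_edges(), rng)
        assert dict(g.degree) == dict(rewired.degree)
        w1 = sorted(d["weight"] for _, _, d in g.edges(data=True))
        w2 = sorted(d["weight"] for _, _, d in rewired.edges(data=True))
        assert np.allclose(w1, w2)
        assert set(g.edges) != set(rewired.edges)  # something actually moved

    def test_star_admits_no_swap(self, rng):
        g = generate_toy_graph("star", 6)
        with pytest.raises(ValueError, match="no degree-preserving swap"):
            weighted_double_edge_swap(g, 10, rng)

    def test_p_value_counting_rule(self):
        # null |d| draws (0.1, 0.2, 0.3, 0.4), observed 0.35:
        # one draw >= 0.35 -> p = (1+1)/(4+1)
        null = np.array([[0.1], [0.2], [-0.3], [0.4]])
        p = permutation_pvalues(null, np.array([0.35]))
        assert p[0] == pytest.approx(0.4)
        # p never 0, never above 1
        p_hi = permutation_pvalues(null, np.array([99.0]))
        assert p_hi[0] == pytest.approx(0.2)
        p_lo = permutation_pvalues(null, np.array([0.0]))
        assert p_lo[0] == 1.0

    def test_identical_networks_are_not_flagged(self, rng):
        g = oracles.random_weighted_graph(rng, 12, 0.5)
        res = rewire_permutation_test(g, g.copy(), n_perm=99, seed=1)
        assert all(v == 0.0 for v in res.observed.values())
        assert all(p > 0.9 for p in res.p_value.values())

    def test_mismatched_node_sets_rejected(self, rng):
        g = oracles.random_weighted_graph(rng, 6, 0.8)
        h = oracles.random_weighted_graph(rng, 7, 0.8)
        with pytest.raises(ValueError, match="node set"):
            rewire_permutation_test(g, h, n_perm=10, seed=0)

    def test_deterministic_given_seed(self, rng):
        g = oracles.random_weighted_graph(rng, 10, 0.5)
        h = oracles.random_weighted_graph(rng, 10, 0.5)
        h.add_nodes_from(g.nodes)
        g.add_nodes_from(h.nodes)
        r1 = rewire_permutation_test(g, h, n_perm=50, seed=42)
        r2 = rewire_permutation_test(g, h, n_perm=50, seed=42)
        assert r1.p_value == r2.p_value


class TestBehaviorCorrelation:
    def _hub_frame(self, values):
        return pd.DataFrame({"dCA1": values},
                            index=[f"a{i}" for i in range(len(values))])

    def test_proportional_behavior_gives_r_one(self):
        hub = self._hub_frame([0.1, 0.3, 0.5, 0.9])
        perf = pd.Series([10.0, 30.0, 50.0, 90.0], index=hub.index)
        out = behavior_hub_correlation(hub, perf)
        assert out.loc["dCA1", "r"] == pytest.approx(1.0)
        assert out.loc["dCA1", "n"] == 4

    def test_matches_closed_form_pearson(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 6, 9])
        r_hand = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        out = behavior_hub_correlation(
            self._hub_frame(x), pd.Series(y, index=[f"a{i}" for i in range(4)]))
        assert out.loc["dCA1", "r"] == pytest.approx(r_hand, abs=1e-12)

    def test_independent_behavior_gives_mean_r_near_zero(self):
        rs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            hub = self._hub_frame(rng.uniform(size=8))
            perf = pd.Series(rng.uniform(40, 90, size=8), index=hub.index)
            rs.append(behavior_hub_correlation(hub, perf).loc["dCA1", "r"])
        assert abs(np.mean(rs)) < 0.08

    def test_zero_variance_rejected(self):
        hub = self._hub_frame([0.5, 0.5, 0.5, 0.5])
        perf = pd.Series([1.0, 2.0, 3.0, 4.0], index=hub.index)
        with pytest.raises(ValueError, match="zero variance"):
            behavior_hub_correlation(hub, perf)
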