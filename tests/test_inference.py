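"""Group t-tests, BH-FDR, cluster extraction, slope regression: oracles + calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sfmvpa as m
from sfmvpa.inference import extract_clusters, fdr_mask


def bfs_components(mask, adjacency):
    """Independent connected-components oracle (breadth-first search)."""
    nodes = [i for i, keep in enumerate(mask) if keep]
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            u = queue.pop()
            if u in comp:
                continue
            comp.add(u)
            queue.extend(v for v in nodes if adjacency[u][v] and v not in comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestTTestVsChance:
    def test_two_subject_closed_form(self):
        """{0.55, 0.65} vs 0.5: t=2 with 1 df; p = 0.5 - arctan(2)/pi."""
        stat = m.ttest_vs_chance(np.array([[0.55], [0.65]]), 0.5)
        assert stat.t[0] == pytest.approx(2.0)
        assert stat.p[0] == pytest.approx(0.5 - np.arctan(2.0) / np.pi, abs=1e-10)
        assert stat.p[0] == pytest.approx(0.1476, abs=5e-5)

    def test_all_at_chance_convention(self):
        stat = m.ttest_vs_chance(np.full((5, 3), 0.5), 0.5)
        assert np.all(stat.t == 0) and np.all(stat.p == 0.5)

    def test_zero_variance_above_chance_degenerate(self):
        stat = m.ttest_vs_chance(np.full((4, 2), 0.8), 0.5)
        assert np.all(stat.p == 0) and np.all(stat.degenerate)

    def test_below_chance_one_sided(self):
        stat = m.ttest_vs_chance(np.array([[0.40], [0.42], [0.38]]), 0.5)
        assert stat.p[0] > 0.5

    def test_fewer_than_two_subjects(self):
        with pytest.raises(ValueError):
            m.ttest_vs_chance(np.array([[0.6]]), 0.5)

    def test_type_one_error_calibrated(self):
        """Gaussian null accuracies: rejection rate at alpha within binomial CI."""
        rng = np.random.default_rng(4)
        maps = rng.normal(0.5, 0.05, size=(12, 10_000))
        stat = m.ttest_vs_chance(maps, 0.5)
        alpha = 0.05
        rate = np.mean(stat.p < alpha)
        se = np.sqrt(alpha * (1 - alpha) / maps.shape[1])
        assert abs(rate - alpha) < 4 * se


class TestFdr:
    def test_worked_example(self):
        mask = fdr_mask(np.array([0.001, 0.02, 0.03, 0.9]), q=0.05)
        assert np.array_equal(mask, [True, True, True, False])

    def test_all_zero_all_one(self):
        assert fdr_mask(np.zeros(5), 0.01).all()
        assert not fdr_mask(np.ones(5), 0.01).any()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(seed).uniform(size=200) ** 2
        for q in (0.01, 0.05, 0.2):
            ref = multipletests(p, alpha=q, method="fdr_bh")[0]
            assert np.array_equal(fdr_mask(p, q), ref)

    def test_monotone_in_q(self):
        p = np.random.default_rng(9).uniform(size=100)
        r1, r2 = fdr_mask(p, 0.01), fdr_mask(p, 0.1)
        assert np.all(r2[r1])  # rejections(q1) subset of rejections(q2)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_property_matches_reference_and_threshold_shape(self, ps, q):
        """BH rejections agree with the reference implementation and are a
        lower set of the sorted p-values."""
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(ps)
        mask = fdr_mask(p, q)
        assert np.array_equal(mask, multipletests(p, alpha=q, method="fdr_bh")[0])
        if mask.any() and (~mask).any():
            assert p[mask].max() <= p[~mask].min()  # the k smallest are rejected


class TestClusters:
    def _chain_adjacency(self, n=10):
        adj = np.zeros((n, n), bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        return adj

    def test_empty_mask(self):
        assert len(extract_clusters(np.zeros(5, bool), self._chain_adjacency(5))) == 0

    def test_chain_two_components(self):
        mask = np.zeros(10, bool)
        mask[[1, 2, 3, 7, 8]] = True
        cs = extract_clusters(mask, self._chain_adjacency())
        got = {frozenset(c.members.tolist()) for c in cs}
        assert got == {frozenset({1, 2, 3}), frozenset({7, 8})}
        assert sorted(c.size for c in cs) == [2, 3]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        adj = rng.random((n, n)) < 0.02
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        mask = rng.random(n) < 0.4
        cs = extract_clusters(mask, adj)
        got = {frozenset(c.members.tolist()) for c in cs}
        assert got == bfs_components(mask, adj)

    def test_relabeling_invariance(self):
        # permuting label ids permutes the components and nothing else
        rng = np.random.default_rng(3)
        n = 60
        adj = rng.random((n, n)) < 0.05
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        mask = rng.random(n) < 0.5
        perm = rng.permutation(n)
        base = {frozenset(c.members.tolist()) for c in extract_clusters(mask, adj)}
        permuted = {frozenset(perm[c.members].tolist())
                    for c in extract_clusters(mask[perm], adj[np.ix_(perm, perm)])}
        assert base == permuted

    def test_areas_and_peak(self):
        adj = self._chain_adjacency(4)
        mask = np.array([True, True, False, True])
        stat = m.StatMap(t=np.array([1.0, -5.0, 0.0, 2.0]), p=np.zeros(4), effect=np.zeros(4))
        cs = extract_clusters(mask, adj, stat=stat, areas=np.array([1.0, 2.0, 4.0, 8.0]))
        by_size = sorted(cs, key=lambda c: c.size)
        assert by_size[1].area_mm2 == pytest.approx(3.0)
        assert by_size[1].peak == 1  # max |t|


class TestSignificantMap:
    def _ring_adjacency(self, n):
        adj = np.zeros((n, n), bool)
        for i in range(n):
            adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = True
        return adj

    def test_strict_min_cluster_size(self):
        n = 30
        adj = self._ring_adjacency(n)
        p = np.ones(n)
        p[:10] = 1e-9  # a 10-label contiguous cluster
        stat = m.StatMap(t=np.full(n, 8.0), p=p, effect=np.full(n, 0.7))
        cs = m.significant_map(stat, adj, p_thresh=1e-4, fdr_q=0.01, min_cluster_labels=10)
        assert len(cs) == 0  # strictly more than 10 required
        p[:11] = 1e-9
        cs = m.significant_map(m.StatMap(t=stat.t, p=p, effect=stat.effect), adj)
        assert len(cs) == 1 and cs.clusters[0].size == 11

    def test_null_maps_rarely_yield_clusters(self):
        """Chance-level accuracy maps: zero surviving clusters in >=95% of replicates."""
        rng = np.random.default_rng(6)
        n_lab, n_sub, reps = 102, 20, 100
        adj = self._ring_adjacency(n_lab)
        empty = 0
        for _ in range(reps):
            # binomial accuracies: 40 test trials at chance, as decoding yields
            maps = rng.binomial(40, 0.5, size=(n_sub, n_lab)) / 40.0
            stat = m.ttest_vs_chance(maps, 0.5)
            cs = m.significant_map(stat, adj)
            empty += len(cs) == 0
        assert empty >= 0.95 * reps


class TestGroupSlope:
    def test_constant_values_p_one(self):
        stat = m.group_slope_test(np.full((5, 4, 3), 2.0))
        assert np.all(stat.effect == 0) and np.all(stat.p == 1.0)

    def test_exact_linear_slope(self):
        loads = np.arange(1, 5, dtype=float)
        values = np.tile(2 * loads, (6, 1))[:, :, None]  # value = 2*load, all subjects
        stat = m.group_slope_test(values)
        assert np.allclose(stat.effect, 2.0)

    def test_simulated_slopes_recovered(self):
        rng = np.random.default_rng(8)
        loads = np.arange(1, 5, dtype=float)
        hits = 0
        for _ in range(20):
            slopes = 1 + rng.normal(0, 0.1, size=20)
            values = slopes[:, None] * loads[None, :] + rng.normal(0, 0.01, (20, 4))
            stat = m.group_slope_test(values[:, :, None])
            hits += (0.9 <= stat.effect[0] <= 1.1) and stat.p[0] < 1e-8
        assert hits >= 19

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            m.group_slope_test(np.zeros((1, 4)))
        with pytest.raises(ValueError):
            m.group_slope_test(np.zeros((3, 1)))
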