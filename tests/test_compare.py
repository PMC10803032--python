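"""Network comparison: probabilities, metabolic network, weighted paths."""

import itertools

import numpy as np
import pytest

from isletnet.compare import (
    CalibrationError,
    build_metabolic_network,
    comparison_probabilities,
    sync_stratified_path_comparison,
    weighted_shortest_paths,
)
from isletnet.funcnet import FunctionalNetwork
from isletnet.islet import CellParameters, IsletGeometry, StructuralNetwork


def _fnet(adj):
    adj = np.asarray(adj, dtype=bool)
    return FunctionalNetwork(adjacency=adj, R_th=0.9, valid=np.ones(len(adj), dtype=bool))


def _edges_to_adj(n, edges):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return adj


class TestComparisonProbabilities:
    def test_identical_networks(self):
        adj = _edges_to_adj(5, [(0, 1), (2, 3)])
        stats = comparison_probabilities(_fnet(adj), adj)
        assert stats.pr_sync_given_other == 1.0
        assert stats.pr_other_given_sync == 1.0

    def test_four_cell_hand_example(self):
        """sync = {AB, AC}, GJ = {AB, BD} over 6 pairs → both conditionals ½."""
        sync = _edges_to_adj(4, [(0, 1), (0, 2)])
        gj = _edges_to_adj(4, [(0, 1), (1, 3)])
        stats = comparison_probabilities(_fnet(sync), gj)
        assert stats.pr_sync == pytest.approx(2 / 6)
        assert stats.pr_other == pytest.approx(2 / 6)
        assert stats.pr_both == pytest.approx(1 / 6)
        assert stats.pr_sync_given_other == pytest.approx(0.5)
        assert stats.pr_other_given_sync == pytest.approx(0.5)

    def test_bayes_identity_and_bounds_on_random_networks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            a = rng.random((n, n)) < 0.3
            b = rng.random((n, n)) < 0.4
            a = np.triu(a, 1)
            b = np.triu(b, 1)
            stats = comparison_probabilities(_fnet(a | a.T), b | b.T)
            assert stats.pr_both <= min(stats.pr_sync, stats.pr_other) + 1e-15
            if stats.m_other and stats.m_sync:
                lhs = stats.pr_sync_given_other * stats.pr_other
                rhs = stats.pr_other_given_sync * stats.pr_sync
                assert lhs == pytest.approx(stats.pr_both, abs=1e-12)
                assert rhs == pytest.approx(stats.pr_both, abs=1e-12)

    def test_undefined_conditional_when_other_empty(self):
        sync = _edges_to_adj(4, [(0, 1)])
        stats = comparison_probabilities(_fnet(sync), np.zeros((4, 4), dtype=bool))
        assert np.isnan(stats.pr_sync_given_other)


class TestMetabolicNetwork:
    def _geom_params(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 10, (n, 3))
        geom = IsletGeometry(positions=pos, coupling_cutoff=2.35)
        params = CellParameters(
            k_glyc=np.abs(rng.normal(1.26e-4, 3.15e-5, n)),
            g_KATP=np.full(n, 2.31),
            g_coup_cell=np.full(n, 0.12),
        )
        return geom, params

    def test_distance_constraint_holds(self, fast_batch):
        rec = fast_batch[0]
        islet = rec["islet"]
        met = build_metabolic_network(islet.params, islet.geometry, rec["fnet"], islet.structure)
        dist = islet.geometry.pairwise_distances()
        i, j = np.nonzero(np.triu(met.adjacency, 1))
        assert (dist[i, j] <= 0.15 * islet.geometry.islet_diameter + 1e-12).all()

    def test_calibration_matches_target_within_tolerance(self, fast_batch):
        for rec in fast_batch[:2]:
            islet = rec["islet"]
            met = build_metabolic_network(
                islet.params, islet.geometry, rec["fnet"], islet.structure
            )
            stats = comparison_probabilities(rec["fnet"], met)
            target = comparison_probabilities(rec["fnet"], islet.structure).pr_sync_given_other
            assert abs(stats.pr_sync_given_other - target) <= 0.01

    def test_disjoint_halves_no_cross_edges_below_gap(self):
        """Two spatial halves with disjoint k_glyc ranges: a cutoff smaller
        than the range gap admits no cross-half metabolic edge."""
        n = 20
        pos = np.zeros((n, 3))
        pos[:, 0] = np.concatenate([np.linspace(0, 2, 10), np.linspace(8, 10, 10)])
        geom = IsletGeometry(positions=pos, coupling_cutoff=2.35)
        k = np.concatenate([np.linspace(1.0, 1.1, 10), np.linspace(2.0, 2.1, 10)]) * 1e-4
        params = CellParameters(k_glyc=k, g_KATP=np.full(n, 2.31), g_coup_cell=np.full(n, 0.12))
        fnet = _fnet(np.zeros((n, n), dtype=bool))
        struct = StructuralNetwork(adjacency=_edges_to_adj(n, [(0, 1)]))
        met = build_metabolic_network(
            params, geom, fnet, struct, distance_fraction=1.0, similarity_cutoff=0.5e-4
        )
        half = np.zeros(n, dtype=bool)
        half[:10] = True
        cross = met.adjacency[np.ix_(half, ~half)]
        assert not cross.any()
        assert met.n_edges > 0  # within-half edges do exist


class TestWeightedShortestPaths:
    def _net(self, n, edges_with_g):
        adj = np.zeros((n, n), dtype=bool)
        ec = np.zeros((n, n))
        for i, j, g in edges_with_g:
            adj[i, j] = adj[j, i] = True
            ec[i, j] = ec[j, i] = g
        return StructuralNetwork(adjacency=adj, edge_conductance=ec)

    def test_direct_pair(self):
        net = self._net(2, [(0, 1, 0.2)])
        res = weighted_shortest_paths(net)
        assert res.hops[0, 1] == 1
        assert res.cumulative_weight[0, 1] == pytest.approx(0.2)

    def test_high_conductance_route_preferred(self):
        """A–B–C at conductance 0.2 (resistance 10) beats A–D–C at 0.05
        (resistance 40); cumulative weight along the chosen path is 0.4."""
        net = self._net(4, [(0, 1, 0.2), (1, 2, 0.2), (0, 3, 0.05), (3, 2, 0.05)])
        res = weighted_shortest_paths(net)
        assert res.hops[0, 2] == 2
        assert res.cumulative_weight[0, 2] == pytest.approx(0.4)
        assert res.normalized_weight[0, 2] == pytest.approx(0.2)

    def test_uniform_weights_match_hop_paths(self):
        rng = np.random.default_rng(5)
        n = 12
        adj = np.triu(rng.random((n, n)) < 0.25, 1)
        adj = adj | adj.T
        net = StructuralNetwork(adjacency=adj, edge_conductance=np.where(adj, 0.1, 0.0))
        res = weighted_shortest_paths(net)
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import shortest_path

        hops = shortest_path(csr_matrix(adj), directed=False, unweighted=True)
        connected = np.isfinite(hops) & ~np.eye(n, dtype=bool)
        np.testing.assert_array_equal(res.hops[connected], hops[connected].astype(int))

    def test_matches_exhaustive_enumeration_small_graphs(self):
        """Least-resistance totals agree with brute-force path enumeration."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(4, 8))
            adj = np.triu(rng.random((n, n)) < 0.45, 1)
            adj = adj | adj.T
            g = np.where(adj, rng.uniform(0.05, 0.3, (n, n)), 0.0)
            g = np.triu(g, 1)
            g = g + g.T
            if not adj.any():
                continue
            net = StructuralNetwork(adjacency=adj, edge_conductance=g)
            res = weighted_shortest_paths(net)
            # brute force: enumerate all simple paths
            for s in range(n):
                for t in range(n):
                    if s == t:
                        continue
                    best = np.inf
                    stack = [(s, (s,), 0.0)]
                    while stack:
                        node, path, resist = stack.pop()
                        if node == t:
                            best = min(best, resist)
                            continue
                        for nb in np.flatnonzero(adj[node]):
                            if nb not in path:
                                stack.append((nb, path + (nb,), resist + 1.0 / g[node, nb]))
                    if np.isinf(best):
                        assert res.hops[s, t] == -1
                    else:
                        assert res.hops[s, t] >= 1
                        assert res.total_resistance[s, t] == pytest.approx(best, rel=1e-9)

    def test_nonpositive_weight_rejected(self):
        net = self._net(3, [(0, 1, 0.2), (1, 2, 0.0)])
        # zero-conductance edge present in adjacency
        with pytest.raises(ValueError):
            weighted_shortest_paths(net)


class TestSyncStratifiedComparison:
    def _islet_paths(self, seed, planted=True):
        """Chain islet where synchronized pairs ride high-conductance edges."""
        rng = np.random.default_rng(seed)
        n = 20
        edges = [(i, i + 1, 0.3 if i < 10 else 0.05) for i in range(n - 1)]
        adj = np.zeros((n, n), dtype=bool)
        ec = np.zeros((n, n))
        for i, j, g in edges:
            adj[i, j] = adj[j, i] = True
            ec[i, j] = ec[j, i] = g
        net = StructuralNetwork(adjacency=adj, edge_conductance=ec)
        paths = weighted_shortest_paths(net)
        sync = np.zeros((n, n), dtype=bool)
        if planted:  # synchronized pairs live on the high-g half
            for i in range(9):
                for j in range(i + 1, min(i + 4, 10)):
                    sync[i, j] = sync[j, i] = True
        else:  # arbitrary pair labels
            m = np.triu(rng.random((n, n)) < 0.15, 1)
            sync = m | m.T
        return paths, _fnet(sync)

    def test_planted_high_conductance_sync_pairs_score_higher(self):
        islets = [self._islet_paths(s) for s in range(4)]
        out = sync_stratified_path_comparison(islets, max_distance=3)
        tests = out["tests"]
        assert (tests["mean_sync_norm"] > tests["mean_nonsync_norm"]).all()

    def test_permuted_labels_indistinguishable(self):
        islets = [self._islet_paths(s, planted=False) for s in range(5)]
        out = sync_stratified_path_comparison(islets, max_distance=3)
        # no stratum should be flagged significant at the corrected alpha
        assert not out["tests"]["significant"].any()

    def test_fifteen_strata_alpha(self):
        islets = [self._islet_paths(s) for s in range(2)]
        out = sync_stratified_path_comparison(islets, max_distance=15)
        assert out["per_test_alpha"] == pytest.approx(0.05 / 15)
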