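"""Islet construction: geometry, structural wiring, heterogeneity."""

import numpy as np
import pytest

from isletnet.islet import (
    DEGREE_SPECS,
    CellParameters,
    DegreeSpec,
    IsletGeometry,
    StructuralNetwork,
    assign_edge_conductances,
    build_geometry,
    build_islet,
    build_structural_network,
    sample_heterogeneity,
)


class TestGeometry:
    def test_two_cells_diameter_is_their_distance(self):
        g = build_geometry(2, seed=0)
        d = np.linalg.norm(g.positions[0] - g.positions[1])
        assert g.islet_diameter == pytest.approx(d)

    def test_rejects_single_cell(self):
        with pytest.raises(ValueError):
            build_geometry(1, seed=0)

    def test_deterministic_for_fixed_seed(self):
        a = build_geometry(1000, seed=1)
        b = build_geometry(1000, seed=1)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_packing_supports_max_degree(self):
        """Interior cells must have enough proximal neighbors to admit the
        maximum configured gap-junction degree (12)."""
        g = build_geometry(1000, seed=1)
        d = g.pairwise_distances()
        np.fill_diagonal(d, np.inf)
        counts = (d <= g.coupling_cutoff).sum(axis=1)
        # interior = cells in the inner half-radius of the cluster
        center = g.positions.mean(axis=0)
        r = np.linalg.norm(g.positions - center, axis=1)
        interior = r < np.median(r)
        assert np.median(counts[interior]) >= 12
        # nearest-neighbor spacing is tight and unimodal around d_min
        nn = d.min(axis=1)
        assert nn.min() >= 1.0
        assert np.median(nn) < 1.5


class TestStructuralNetwork:
    def test_adjacency_invariants(self, small_islet):
        adj = small_islet.structure.adjacency
        np.testing.assert_array_equal(adj, adj.T)
        assert not np.diag(adj).any()

    def test_mean_degree_matches_target_over_islets(self):
        degs = []
        for seed in range(5):
            g = build_geometry(1000, seed=seed)
            net = build_structural_network(g, DEGREE_SPECS["fast"], seed=seed + 100)
            assert net.degrees.min() >= 1 and net.degrees.max() <= 12
            degs.append(net.degrees)
        grand_mean = np.concatenate(degs).mean()
        assert grand_mean == pytest.approx(5.25, abs=0.15)

    def test_iom_degree_spec(self):
        g = build_geometry(260, seed=4)
        net = build_structural_network(g, DEGREE_SPECS["iom"], seed=4)
        assert net.degrees.min() >= 1 and net.degrees.max() <= 14
        assert net.degrees.mean() == pytest.approx(6.01, abs=0.7)

    def test_degenerate_sd_zero_gives_exact_degrees(self):
        g = build_geometry(30, seed=2)
        net = build_structural_network(g, DegreeSpec(mean=2, sd=0, lo=1, hi=12), seed=0)
        assert (net.degrees == 2).all()


class TestHeterogeneity:
    def test_fast_pooled_means(self):
        pooled = [sample_heterogeneity(1000, "fast", seed=s) for s in range(5)]
        k = np.concatenate([p.k_glyc for p in pooled])
        assert k.mean() == pytest.approx(1.26e-4, rel=0.02)
        gk = np.concatenate([p.g_KATP for p in pooled])
        assert gk.mean() == pytest.approx(2.31, rel=0.02)

    def test_gcoup_gamma_rescaling_mean_and_cv(self):
        """Multiplicative rescaling preserves the gamma shape: CV = 1/√k = 0.5,
        so the sd follows the mean (0.06 nS at mean 0.12 nS)."""
        p = sample_heterogeneity(1000, "fast", seed=11)
        g = p.g_coup_cell
        assert g.mean() == pytest.approx(0.12, abs=1e-12)
        assert g.std() / g.mean() == pytest.approx(0.5, abs=0.05)

    def test_iom_means(self):
        p = sample_heterogeneity(1000, "iom", seed=3)
        assert p.k_glyc.mean() == pytest.approx(0.0037, rel=0.03)
        assert p.g_KATP.mean() == pytest.approx(19700, rel=0.03)

    def test_all_values_strictly_positive(self):
        # IOM coupling N(1, 0.5) would go negative without the resample rule
        p = sample_heterogeneity(2000, "iom", seed=9)
        assert (p.g_coup_cell > 0).all()

    def test_zero_sd_override_gives_homogeneous_islet(self):
        p = sample_heterogeneity(
            50,
            "fast",
            seed=0,
            overrides={
                "k_glyc": ("normal", 1.26e-4, 0.0),
                "g_KATP": ("normal", 2.31, 0.0),
                "g_coup": ("normal", 0.12, 0.0),
            },
        )
        assert np.ptp(p.k_glyc) == 0 and np.ptp(p.g_KATP) == 0 and np.ptp(p.g_coup_cell) == 0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            sample_heterogeneity(10, "fast", seed=0, overrides={"k_glyc": ("normal", -1.0, 0.1)})


class TestEdgeConductances:
    def _chain(self, gvals):
        """3-cell chain 1-0, 0-2 with per-cell coupling parameters."""
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        adj[0, 2] = adj[2, 0] = True
        net = StructuralNetwork(adjacency=adj)
        params = CellParameters(
            k_glyc=np.full(3, 1e-4), g_KATP=np.full(3, 2.3), g_coup_cell=np.asarray(gvals)
        )
        return assign_edge_conductances(net, params)

    def test_hand_example(self):
        """A 0.10 nS cell linked to 0.14 and 0.10 nS neighbors carries edges
        of 0.12 and 0.10 nS, total 0.22 nS."""
        net = self._chain([0.10, 0.14, 0.10])
        assert net.edge_conductance[0, 1] == pytest.approx(0.12)
        assert net.edge_conductance[0, 2] == pytest.approx(0.10)
        assert net.total_conductance[0] == pytest.approx(0.22)

    def test_homogeneous_total(self, small_islet):
        params = CellParameters(
            k_glyc=np.full(30, 1e-4),
            g_KATP=np.full(30, 2.3),
            g_coup_cell=np.full(30, 0.12),
        )
        net = assign_edge_conductances(small_islet.structure, params)
        np.testing.assert_allclose(net.total_conductance, 0.12 * net.degrees)

    def test_linearity_under_scaling(self, small_islet):
        p = small_islet.params
        half = CellParameters(
            k_glyc=p.k_glyc, g_KATP=p.g_KATP, g_coup_cell=0.5 * p.g_coup_cell
        )
        net = assign_edge_conductances(small_islet.structure, half)
        np.testing.assert_allclose(
            net.edge_conductance, 0.5 * small_islet.structure.edge_conductance
        )
        np.testing.assert_allclose(
            net.total_conductance, 0.5 * small_islet.structure.total_conductance
        )

    def test_total_matches_brute_force_pair_sum(self, small_islet):
        net = small_islet.structure
        g = small_islet.params.g_coup_cell
        n = net.n_cells
        brute = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if net.adjacency[i, j]:
                    brute[i] += 0.5 * (g[i] + g[j])
        np.testing.assert_allclose(net.total_conductance, brute, rtol=1e-12)

    def test_mismatched_lengths_rejected(self, small_islet):
        params = CellParameters(
            k_glyc=np.full(5, 1e-4), g_KATP=np.full(5, 2.3), g_coup_cell=np.full(5, 0.1)
        )
        with pytest.raises(ValueError):
            assign_edge_conductances(small_islet.structure, params)


def test_build_islet_deterministic():
    a = build_islet(40, "fast", seed=5)
    b = build_islet(40, "fast", seed=5)
    np.testing.assert_array_equal(a.geometry.positions, b.geometry.positions)
    np.testing.assert_array_equal(a.structure.adjacency, b.structure.adjacency)
    np.testing.assert_array_equal(a.params.k_glyc, b.params.k_glyc)
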