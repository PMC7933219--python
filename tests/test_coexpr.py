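import numpy as np
import pytest

import oracles
from diffconn import coexpr
from diffconn.simulate import SimulationConfig, simulate_two_condition_expression
from conftest import make_matrix


class TestCorrelationMatrix:
    def test_identical_profiles_r_one(self):
        base = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        em = make_matrix([base, base])
        C = coexpr.correlation_matrix(em, "EC")
        assert C.loc["g0", "g1"] == pytest.approx(1.0)

    def test_negated_profile_r_minus_one(self):
        em = make_matrix([[1.0, 2.0, 3.0, 0, 0, 0], [-1.0, -2.0, -3.0, 0, 0, 0]])
        C = coexpr.correlation_matrix(em, "EC")
        assert C.loc["g0", "g1"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        vals = rng.normal(size=(5, 12))
        em = make_matrix(vals)
        C = coexpr.correlation_matrix(em, "EC")
        for i in range(5):
            for j in range(5):
                expected = oracles.pearson_direct(vals[i, :6], vals[j, :6])
                assert C.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_feature_undefined(self):
        em = make_matrix([[5.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        C = coexpr.correlation_matrix(em, "EC")
        assert np.isnan(C.loc["g0", "g1"])
        assert C.loc["g0", "g0"] == 1.0  # unit diagonal kept

    def test_symmetry_and_unit_diagonal(self, rng):
        em = make_matrix(rng.normal(size=(8, 10)))
        C = coexpr.correlation_matrix(em, "TC-EC").to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_spearman_invariant_to_monotone_transform(self, rng):
        vals = rng.normal(size=(4, 10))
        em1 = make_matrix(vals)
        em2 = make_matrix(np.exp(vals))
        C1 = coexpr.correlation_matrix(em1, "EC", method="spearman")
        C2 = coexpr.correlation_matrix(em2, "EC", method="spearman")
        np.testing.assert_allclose(C1.to_numpy(), C2.to_numpy(), atol=1e-12)

    def test_two_samples_warns(self):
        em = make_matrix([[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            coexpr.correlation_matrix(em, "EC")

    def test_absent_condition_rejected(self, tiny_em):
        with pytest.raises(ValueError, match="nope"):
            coexpr.correlation_matrix(tiny_em, "nope")


class TestBuildNetwork:
    def corr_from(self, rng, n=10, samples=8):
        em = make_matrix(rng.normal(size=(n, 2 * samples)), n_per_cond=samples)
        return coexpr.correlation_matrix(em, "EC")

    def test_threshold_one_keeps_only_perfect_pair(self):
        base = [1.0, 2.0, 3.0, 4.0]
        em = make_matrix([base * 2, base * 2, [1, 5, 2, 9, 1, 5, 2, 9]], n_per_cond=4)
        net = coexpr.build_network(coexpr.correlation_matrix(em, "EC"), 1.0)
        assert net.n_edges == 1
        assert net.graph.has_edge("g0", "g1")

    def test_threshold_above_all_gives_empty_network(self, rng):
        C = self.corr_from(rng)
        C.values[~np.eye(len(C), dtype=bool)] = 0.1
        net = coexpr.build_network(C, 0.9)
        assert net.n_edges == 0 and net.max_degree == 0

    def test_edge_set_equals_brute_force_scan(self, rng):
        C = self.corr_from(rng, n=15)
        thr = 0.4
        net = coexpr.build_network(C, thr)
        ids = list(C.index)
        expected = {
            frozenset((ids[i], ids[j]))
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if abs(C.iloc[i, j]) >= thr
        }
        got = {frozenset(e) for e in net.graph.edges}
        assert got == expected

    def test_nan_correlations_never_form_edges(self):
        em = make_matrix([[5.0] * 8, list(range(8)), list(range(8))], n_per_cond=4)
        net = coexpr.build_network(coexpr.correlation_matrix(em, "EC"), 0.5)
        assert net.degree_of("g0") == 0
        assert net.graph.has_edge("g1", "g2")

    def test_invalid_threshold_rejected(self, rng):
        C = self.corr_from(rng)
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                coexpr.build_network(C, bad)

    def test_raising_threshold_never_adds_edges(self, rng):
        C = self.corr_from(rng, n=20)
        edges = [
            {frozenset(e) for e in coexpr.build_network(C, t).graph.edges}
            for t in (0.2, 0.4, 0.6, 0.8)
        ]
        for lower, higher in zip(edges, edges[1:]):
            assert higher <= lower


class TestNodeDegrees:
    def test_star_graph_degrees(self):
        import networkx as nx

        G = nx.star_graph(5)  # hub 0, leaves 1..5
        net = coexpr.CoexpressionNetwork("EC", G, 0.5)
        deg = coexpr.node_degrees(net).set_index("feature_id")
        assert deg.loc[0, "degree"] == 5 and deg.loc[0, "normalized_degree"] == 1.0
        assert deg.loc[1, "degree"] == 1 and deg.loc[1, "normalized_degree"] == 0.2

    def test_empty_network_all_zero(self):
        import networkx as nx

        G = nx.empty_graph(4)
        net = coexpr.CoexpressionNetwork("EC", G, 0.5)
        deg = coexpr.node_degrees(net)
        assert (deg["degree"] == 0).all() and (deg["normalized_degree"] == 0).all()

    def test_degrees_equal_adjacency_row_sums(self, rng):
        em = make_matrix(rng.normal(size=(12, 16)), n_per_cond=8)
        C = coexpr.correlation_matrix(em, "EC")
        net = coexpr.build_network(C, 0.3)
        A = (np.abs(C.to_numpy()) >= 0.3).astype(int)
        np.fill_diagonal(A, 0)
        deg = coexpr.node_degrees(net).set_index("feature_id")["degree"]
        np.testing.assert_array_equal(deg[list(C.index)].to_numpy(), A.sum(axis=1))

    def test_degree_sum_is_twice_edge_count(self, rng):
        em = make_matrix(rng.normal(size=(15, 14)), n_per_cond=7)
        net = coexpr.condition_network(em, "TC-EC", 0.4)
        deg = coexpr.node_degrees(net)
        assert deg["degree"].sum() == 2 * net.n_edges


class TestModuleSignal:
    def test_module_members_outrank_background_degree(self):
        """Latent-module members accumulate more |r| >= 0.8 edges than
        unstructured features, averaged over seeds."""
        member_deg, background_deg = [], []
        for seed in range(10):
            cfg = SimulationConfig(
                n_coding=500, n_noncoding=0, de_fraction=0.0,
                n_modules=4, module_size=25, n_rewired_hubs=0, seed=seed,
            )
            em, truth = simulate_two_condition_expression(cfg)
            net = coexpr.condition_network(em, "EC", 0.8)
            deg = coexpr.node_degrees(net).set_index("feature_id")["degree"]
            members = sorted(truth.module_of)
            others = sorted(set(em.feature_ids) - set(members))
            member_deg.append(deg[members].mean())
            background_deg.append(deg[others].mean())
        assert np.mean(member_deg) > np.mean(background_deg)
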