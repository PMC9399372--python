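"""Heat diffusion, topological overlap, union graph and hub screening."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import radiosig.omicsnet as om


class TestNetworkLayer:
    def test_rejects_self_loops_and_negative_heat(self):
        G = nx.Graph([("a", "a")])
        with pytest.raises(ValueError, match="self-loop"):
            om.NetworkLayer("protein", G)
        with pytest.raises(ValueError, match="negative"):
            om.NetworkLayer(
                "mutation", nx.path_graph(2), heat=pd.Series([-1.0, 0.5])
            )
        with pytest.raises(ValueError, match="kind"):
            om.NetworkLayer("methylation", nx.Graph())


class TestDiffusion:
    def test_pure_restart_is_diagonal_with_no_subnetworks(self):
        layer = om.NetworkLayer(
            "mutation", nx.path_graph(4), heat=pd.Series([1.0, 0.5, 0.2, 0.1])
        )
        res = om.diffuse_heat(layer, restart_beta=1.0, delta=1e-9, k_min=2)
        E = res.exchanged.to_numpy()
        assert np.allclose(E, np.diag(np.diag(E)))
        assert res.subnetworks == []

    def test_three_node_path_matches_matrix_inverse(self):
        h = np.array([1.0, 0.5, 0.2])
        layer = om.NetworkLayer("cna", nx.path_graph(3), heat=pd.Series(h))
        res = om.diffuse_heat(layer, restart_beta=0.5)
        A = nx.to_numpy_array(nx.path_graph(3))
        W = A / A.sum(axis=0, keepdims=True)
        F = 0.5 * np.linalg.inv(np.eye(3) - 0.5 * W)
        np.testing.assert_allclose(res.exchanged.to_numpy(), F @ np.diag(h), atol=1e-12)

    def test_zero_delta_recovers_layer_components(self):
        G = nx.Graph([(0, 1), (1, 2), (3, 4)])
        layer = om.NetworkLayer(
            "mutation", G, heat=pd.Series(np.full(5, 0.3))
        )
        res = om.diffuse_heat(layer, restart_beta=0.5, delta=0.0, k_min=1)
        assert sorted(map(sorted, res.subnetworks)) == [[0, 1, 2], [3, 4]]

    def test_column_sums_conserve_injected_heat(self):
        rng = np.random.default_rng(0)
        G = nx.gnp_random_graph(12, 0.3, seed=4)
        h = pd.Series(rng.uniform(0.1, 1.0, 12))
        res = om.diffuse_heat(
            om.NetworkLayer("mutation", G, heat=h), restart_beta=0.4
        )
        np.testing.assert_allclose(
            res.exchanged.sum(axis=0).to_numpy(), h.to_numpy(), atol=1e-10
        )

    def test_parameter_validation(self):
        layer = om.NetworkLayer("mutation", nx.path_graph(2), heat=pd.Series([1.0, 1]))
        with pytest.raises(ValueError):
            om.diffuse_heat(layer, restart_beta=0.0)
        with pytest.raises(ValueError):
            om.diffuse_heat(layer, restart_beta=1.5)
        with pytest.raises(ValueError):
            om.diffuse_heat(om.NetworkLayer("protein", nx.path_graph(2)))


class TestTOM:
    def test_uniform_triangle_hand_value(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 0.0)
        tom = om.tom_matrix(A)
        # (0.5*0.5 + 0.5) / (min(1,1) + 1 - 0.5) = 0.75/1.5
        assert tom[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 1, (10, 10))
        A = (A + A.T) / 2
        tom = om.tom_matrix(A)
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)
        assert (tom >= 0).all() and (tom <= 1).all()


class TestCoexpression:
    def _two_block_expr(self, n_samples=30, block=8, seed=2):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=(2, n_samples))
        rows = [u + rng.normal(0, 0.05, n_samples) for _ in range(block)]
        rows += [v + rng.normal(0, 0.05, n_samples) for _ in range(block)]
        genes = [f"g{i}" for i in range(2 * block)]
        return pd.DataFrame(rows, index=genes, columns=[f"S{i}" for i in range(n_samples)])

    def test_two_independent_blocks_give_two_intact_modules(self):
        expr = self._two_block_expr()
        modules, layer = om.coexpression_layer(
            expr, power=6, min_module_size=4, edge_quantile=0.5
        )
        labels = modules.labels
        assert set(labels) == {1, 2}
        first = set(labels.index[labels == labels["g0"]])
        assert first == {f"g{i}" for i in range(8)}
        assert layer.graph.number_of_edges() > 0

    def test_trait_equal_to_eigengene_correlates_perfectly(self):
        expr = self._two_block_expr()
        modules, _ = om.coexpression_layer(expr, min_module_size=4)
        mod = modules.eigengenes.columns[0]
        trait = modules.eigengenes[mod]
        modules2, _ = om.coexpression_layer(expr, trait=trait, min_module_size=4)
        assert modules2.trait_correlations[mod] == pytest.approx(1.0, abs=1e-8)

    def test_constant_genes_dropped_with_warning(self):
        expr = self._two_block_expr()
        expr.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            modules, _ = om.coexpression_layer(expr, min_module_size=4)
        assert modules.dropped == ["flat"]


class TestUnionGraph:
    def test_idempotent_on_identical_layers(self):
        G = nx.gnp_random_graph(10, 0.4, seed=1)
        U = om.union_graph([G, G.copy()])
        assert set(U.edges) == set(G.edges)

    def test_additive_on_disjoint_edge_sets(self):
        G1 = nx.Graph([(0, 1), (2, 3)])
        G2 = nx.Graph([(4, 5)])
        U = om.union_graph([G1, G2])
        assert U.number_of_edges() == 3

    def test_single_candidate_is_isolated_node(self):
        G = nx.Graph([(0, 1)])
        U = om.union_graph([G], candidates={"lonely"})
        assert list(U.nodes) == ["lonely"] and U.degree["lonely"] == 0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            om.union_graph([nx.Graph([(0, 1)])], candidates=set())


from tests_oracles import brute_force_centralities


class TestHubScreen:
    def test_star_center_is_the_only_hub(self):
        report = om.hub_screen(nx.star_graph(3))
        assert report.hubs == [0]
        c = report.centralities
        assert c.loc[0, "betweenness"] == pytest.approx(3.0)
        assert c.loc[0, "closeness"] == pytest.approx(3.0)
        assert c.loc[1, "closeness"] == pytest.approx(2.0)

    def test_regular_graph_has_no_hubs(self):
        assert om.hub_screen(nx.complete_graph(6)).hubs == []

    def test_centralities_match_brute_force_enumeration(self):
        for seed in range(20):
            G = nx.gnp_random_graph(7, 0.35, seed=seed)
            report = om.hub_screen(G)
            btw, harm = brute_force_centralities(G)
            for v in G.nodes:
                assert report.centralities.loc[v, "betweenness"] == pytest.approx(
                    btw[v], abs=1e-9
                )
                assert report.centralities.loc[v, "closeness"] == pytest.approx(
                    harm[v], abs=1e-9
                )

    def test_invariant_under_node_relabeling(self):
        G = nx.gnp_random_graph(8, 0.4, seed=7)
        mapping = {i: f"n{7 - i}" for i in G.nodes}
        H = nx.relabel_nodes(G, mapping)
        a = om.hub_screen(G)
        b = om.hub_screen(H)
        assert sorted(mapping[v] for v in a.hubs) == b.hubs

    def test_classic_closeness_flag(self):
        report = om.hub_screen(nx.star_graph(3), closeness="classic")
        assert report.centralities.loc[0, "closeness"] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            om.hub_screen(nx.star_graph(3), closeness="weird")
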