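"""Correlation statistics, the differential edge rule and graph machinery."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiaging import diffnet

from ._oracles import (
    bfs_shortest_length,
    bh_stepup,
    enumerate_all_shortest_paths,
    hypergeom_upper_tail_exact,
    residual_partial_corr,
)


class TestPairwisePearson:
    def test_hand_fixture_matches_sum_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        X = pd.DataFrame({"a": x, "b": y})
        r, p = diffnet.pairwise_pearson(X)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r.loc["a", "b"] == pytest.approx(num / den, abs=1e-12)
        assert r.loc["a", "a"] == 1.0
        # p matches scipy's pearsonr
        assert p.loc["a", "b"] == pytest.approx(stats.pearsonr(x, y).pvalue, rel=1e-9)

    def test_anticorrelated_pair(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        X = pd.DataFrame({"a": x, "b": -x})
        r, _ = diffnet.pairwise_pearson(X)
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_column_is_nan(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        r, _ = diffnet.pairwise_pearson(X)
        assert np.isnan(r.loc["a", "b"])


class TestPartialCorrelation:
    def test_formula_equals_residualization_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(10, 40)
            z = rng.standard_normal(n)
            X = pd.DataFrame(
                rng.standard_normal((n, 3)) + np.outer(z, rng.uniform(-1, 1, 3)),
                columns=["a", "b", "c"],
            )
            pr, _ = diffnet.partial_correlation(X, z)
            for i, j in [("a", "b"), ("a", "c"), ("b", "c")]:
                oracle = residual_partial_corr(X[i].to_numpy(), X[j].to_numpy(), z)
                assert pr.loc[i, j] == pytest.approx(oracle, abs=1e-10)

    def test_confounder_removal(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(400)
        X = pd.DataFrame(
            {"a": z + 0.5 * rng.standard_normal(400), "b": z + 0.5 * rng.standard_normal(400)}
        )
        r, _ = diffnet.pairwise_pearson(X)
        pr, _ = diffnet.partial_correlation(X, z)
        assert r.loc["a", "b"] > 0.5
        assert abs(pr.loc["a", "b"]) < 0.15

    def test_irrelevant_covariate_changes_nothing(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((300, 2)), columns=["a", "b"])
        X["b"] += 0.8 * X["a"]
        z = rng.standard_normal(300)
        r, _ = diffnet.pairwise_pearson(X)
        pr, _ = diffnet.partial_correlation(X, z)
        assert pr.loc["a", "b"] == pytest.approx(r.loc["a", "b"], abs=0.05)


class TestBhFdr:
    def test_hand_step_up_vector(self):
        q = diffnet.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        q = diffnet.bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_matches_independent_stepup_and_preserves_order(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        q = diffnet.bh_fdr(p)
        assert np.allclose(q, bh_stepup(p), atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestEdgeRule:
    @staticmethod
    def _stats_row(delta_ctrl, delta_nd, q=0.01):
        return pd.DataFrame(
            {
                "site_a": ["x"], "site_b": ["y"],
                "r_ctrl": [0.5], "r_nd": [0.5],
                "pr_ctrl": [0.5 - delta_ctrl], "pr_nd": [0.5 - delta_nd],
                "q_r_ctrl": [q], "q_r_nd": [q], "q_pr_ctrl": [q], "q_pr_nd": [q],
                "delta_ctrl": [delta_ctrl], "delta_nd": [delta_nd],
                "min_q": [q],
            }
        )

    def test_same_sign_deltas_rejected_regardless_of_fdr(self):
        net = diffnet.build_differential_network(self._stats_row(0.2, 0.3), 0.99)
        assert net.graph.number_of_edges() == 0

    def test_opposite_sign_deltas_kept_under_gate(self):
        net = diffnet.build_differential_network(self._stats_row(0.2, -0.3), 0.1)
        assert net.edge_set == {("x", "y")}

    def test_fdr_gate_blocks(self):
        net = diffnet.build_differential_network(self._stats_row(0.2, -0.3, q=0.5), 0.1)
        assert net.graph.number_of_edges() == 0

    def test_between_group_rule_toggle(self):
        s = self._stats_row(0.2, 0.3)
        s.loc[0, ["r_ctrl", "r_nd", "pr_ctrl", "pr_nd"]] = [0.5, -0.5, -0.4, 0.4]
        net = diffnet.build_differential_network(s, 0.1, rule="between-group")
        assert net.edge_set == {("x", "y")}

    def test_null_data_yields_few_edges(self):
        rng = np.random.default_rng(4)
        Xc = pd.DataFrame(rng.standard_normal((80, 30)))
        Xn = pd.DataFrame(rng.standard_normal((80, 30)))
        zc, zn = rng.standard_normal(80), rng.standard_normal(80)
        s = diffnet.compute_pair_stats(Xc, Xn, zc, zn)
        net = diffnet.build_differential_network(s, 0.1)
        assert net.graph.number_of_edges() / len(s) <= 0.05


class TestPowerLaw:
    def test_preferential_attachment_fits_power_law(self):
        g = nx.barabasi_albert_graph(1000, 2, seed=1)
        slope, r = diffnet.power_law_check(g)
        assert slope < -1
        assert r < -0.8

    def test_er_graph_fits_worse(self):
        ba = nx.barabasi_albert_graph(1000, 2, seed=2)
        er = nx.gnm_random_graph(1000, ba.number_of_edges(), seed=2)
        _, r_ba = diffnet.power_law_check(ba)
        _, r_er = diffnet.power_law_check(er)
        assert r_ba < r_er

    def test_star_graph_not_testable(self):
        with pytest.raises(ValueError, match="not testable"):
            diffnet.power_law_check(nx.star_graph(10))


class TestFisherSimilarity:
    @staticmethod
    def _net(edges):
        g = nx.Graph()
        g.add_edges_from(edges)
        return diffnet.DifferentialNetwork(graph=g, edges=pd.DataFrame())

    def test_identical_networks_highly_significant(self):
        nodes = [f"n{i}" for i in range(30)]
        universe = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        edges = universe[:40]
        _, p = diffnet.network_similarity_fisher(self._net(edges), self._net(edges), universe)
        assert p < 1e-20

    def test_matches_hypergeometric_tail_oracle(self):
        # 2x2 table (10, 2, 3, 985): one-sided Fisher p is the
        # hypergeometric upper tail P(X >= 10) with M=12, n=13, N=1000
        table = np.array([[10, 2], [3, 985]])
        _, p = stats.fisher_exact(table, alternative="greater")
        assert p == pytest.approx(hypergeom_upper_tail_exact(10, 12, 13, 1000), rel=1e-9)

    def test_independent_random_edge_sets_not_enriched(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(25)]
        universe = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        small_ps = 0
        for _ in range(40):
            ia = rng.choice(len(universe), 30, replace=False)
            ib = rng.choice(len(universe), 30, replace=False)
            _, p = diffnet.network_similarity_fisher(
                self._net([universe[i] for i in ia]),
                self._net([universe[i] for i in ib]),
                universe,
            )
            small_ps += p < 0.05
        assert small_ps <= 8  # ~5% nominal under the null

    def test_degenerate_margins_give_p_one(self):
        nodes = ["a", "b", "c"]
        universe = [("a", "b"), ("a", "c"), ("b", "c")]
        _, p = diffnet.network_similarity_fisher(self._net([]), self._net([("a", "b")]), universe)
        assert p == 1.0


class TestShortestPaths:
    def test_direct_edge_has_length_one(self):
        g = nx.Graph([("s", "t"), ("s", "m"), ("m", "t")])
        paths = diffnet.shortest_paths(g, ["s"], ["t"])
        assert paths[("s", "t")] == ["s", "t"]

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(6)
        for trial in range(50):
            g = nx.gnp_random_graph(30, 0.12, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            adj = {u: sorted(g.neighbors(u)) for u in g.nodes}
            nodes = sorted(g.nodes)
            sources, targets = nodes[:4], nodes[-4:]
            paths = diffnet.shortest_paths(g, sources, targets)
            for s in sources:
                for t in targets:
                    if s == t:
                        continue
                    expected = bfs_shortest_length(adj, s, t)
                    if expected is None:
                        assert (s, t) not in paths
                    else:
                        assert len(paths[(s, t)]) - 1 == expected

    def test_lexicographic_tie_break(self):
        g = nx.Graph([("s", "b"), ("s", "a"), ("a", "t"), ("b", "t")])
        paths = diffnet.shortest_paths(g, ["s"], ["t"])
        assert paths[("s", "t")] == ["s", "a", "t"]

    def test_disconnected_pair_absent(self):
        g = nx.Graph([("s", "x"), ("t", "y")])
        assert diffnet.shortest_paths(g, ["s"], ["t"]) == {}


class TestBetweenness:
    def test_counts_match_enumeration_on_small_fixture(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(10, 0.35, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        adj = {u: sorted(g.neighbors(u)) for u in g.nodes}
        nodes = sorted(g.nodes)
        sources, targets = nodes[:3], nodes[-3:]
        paths = diffnet.shortest_paths(g, sources, targets)
        counts = diffnet.path_betweenness(paths, nodes=nodes)
        for node in nodes:
            expected = 0
            for (s, t), path in paths.items():
                all_shortest = enumerate_all_shortest_paths(adj, s, t)
                # the returned path is one of the shortest; count interior hits
                assert path in all_shortest
                expected += node in path[1:-1]
            assert counts[node] == expected

    def test_hub_on_every_path_is_extreme(self):
        g = nx.Graph()
        left = [f"l{i}" for i in range(5)]
        right = [f"r{i}" for i in range(5)]
        for l in left:
            g.add_edge(l, "A")
        for r in right:
            g.add_edge(r, "B")
        g.add_edge("A", "B")
        out = diffnet.betweenness_permutation_test(g, left, right, n_perm=200, seed=0)
        assert out.loc["A", "betweenness"] == 25
        assert out.loc["A", "p"] == pytest.approx(1 / 201)

    def test_leaf_never_on_a_path_has_p_one(self):
        g = nx.Graph([("s", "m"), ("m", "t"), ("m", "leaf")])
        out = diffnet.betweenness_permutation_test(g, ["s"], ["t"], n_perm=100, seed=1)
        assert out.loc["leaf", "betweenness"] == 0
        assert out.loc["leaf", "p"] == 1.0
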