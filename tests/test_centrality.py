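"""Centrality measures, size normalisation, oracle equivalence and the
redundancy screen."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pignet.centrality import (
    betweenness,
    betweenness_oracle,
    centrality_table,
    degree,
    eigenvector,
    eigenvector_residual,
    redundancy_screen,
)

from conftest import make_net


def as_dict(records, key="raw"):
    return {r.pig: getattr(r, key) for r in records}


def random_net(rng, directed, weighted, n=None):
    n = n or int(rng.integers(3, 9))
    p = rng.uniform(0.25, 0.6)
    G = nx.DiGraph() if directed else nx.Graph()
    G.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u == v or (not directed and u > v):
                continue
            if rng.random() < p:
                w = float(rng.uniform(0.5, 4.0)) if weighted else 1.0
                G.add_edge(u, v, weight=w)
    return make_net(G)


class TestDegree:
    def test_full_interaction_gives_normalised_one(self):
        G = nx.Graph()
        G.add_nodes_from(range(13))
        for v in range(1, 13):
            G.add_edge(0, v, weight=2.0)
        net = make_net(G, n_nonlittermates=12)
        recs = as_dict(degree(net, "all"), "normalised")
        assert recs[0] == pytest.approx(1.0)

    def test_isolated_node_scores_zero(self):
        G = nx.DiGraph()
        G.add_nodes_from(["a", "b"])
        net = make_net(G, n_nonlittermates=10)
        recs = degree(net, "all")
        assert all(r.raw == 0 and r.normalised == 0 for r in recs)

    def test_one_extra_incoming_edge_raises_indegree_by_one_twelfth(self):
        G = nx.DiGraph()
        G.add_nodes_from(range(13))
        for v in range(1, 5):
            G.add_edge(v, 0, weight=1.0)
        net = make_net(G, n_nonlittermates=12)
        before = as_dict(degree(net, "in"), "normalised")[0]
        G.add_edge(5, 0, weight=1.0)
        after = as_dict(degree(make_net(G, n_nonlittermates=12), "in"), "normalised")[0]
        assert after - before == pytest.approx(1 / 12)
        assert round(after - before, 2) == 0.08

    def test_in_out_modes_require_direction(self):
        net = make_net(nx.Graph([(0, 1)]))
        with pytest.raises(ValueError, match="undirected"):
            degree(net, "in")

    def test_weighted_degree_sums_incident_weight(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=5.0)
        G.add_edge("c", "a", weight=2.0)
        net = make_net(G)
        assert as_dict(degree(net, "all", weighted=True))["a"] == 7.0
        assert as_dict(degree(net, "out", weighted=True))["a"] == 5.0
        assert as_dict(degree(net, "in", weighted=True))["a"] == 2.0

    def test_directed_degree_totals_balance(self, rng=np.random.default_rng(5)):
        for _ in range(20):
            net = random_net(rng, directed=True, weighted=True)
            for wtd in (False, True):
                tot_in = sum(as_dict(degree(net, "in", wtd)).values())
                tot_out = sum(as_dict(degree(net, "out", wtd)).values())
                assert tot_in == pytest.approx(tot_out)


class TestBetweenness:
    def test_middle_of_a_path_carries_the_pair(self):
        net = make_net(nx.Graph([("a", "b"), ("b", "c")]))
        nx.set_edge_attributes(net.graph, 1.0, "weight")
        raw = as_dict(betweenness(net))
        assert raw == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_centre_carries_all_leaf_pairs(self):
        G = nx.star_graph(4)
        nx.set_edge_attributes(G, 1.0, "weight")
        raw = as_dict(betweenness(make_net(G)))
        assert raw[0] == pytest.approx(6.0)  # C(4,2) leaf pairs

    def test_tied_shortest_paths_split_the_credit(self):
        G = nx.cycle_graph(4)  # two equal routes between opposite corners
        nx.set_edge_attributes(G, 1.0, "weight")
        raw = as_dict(betweenness(make_net(G)))
        assert all(v == pytest.approx(0.5) for v in raw.values())

    def test_complete_graph_has_zero_betweenness(self):
        G = nx.complete_graph(6)
        nx.set_edge_attributes(G, 1.0, "weight")
        assert all(v == 0 for v in as_dict(betweenness(make_net(G))).values())

    def test_strong_edges_are_short_paths_when_weighted(self):
        # a-b-c via heavy edges is cheaper than the weak direct a-c edge
        G = nx.Graph()
        G.add_edge("a", "b", weight=10.0)
        G.add_edge("b", "c", weight=10.0)
        G.add_edge("a", "c", weight=1.0)
        raw = as_dict(betweenness(make_net(G), weighted=True))
        assert raw["b"] == pytest.approx(1.0)

    def test_size_normalisation_uses_pair_counts(self):
        net = make_net(nx.Graph([("a", "b"), ("b", "c")]), n_nonlittermates=12)
        nx.set_edge_attributes(net.graph, 1.0, "weight")
        rec = {r.pig: r for r in betweenness(net)}
        n = 13
        assert rec["b"].normalised == pytest.approx(1.0 / ((n - 1) * (n - 2) / 2))

    @pytest.mark.parametrize("directed", [False, True])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_exhaustive_oracle(self, directed, weighted):
        rng = np.random.default_rng(17 + directed + 2 * weighted)
        for _ in range(40):
            net = random_net(rng, directed, weighted)
            got = as_dict(betweenness(net, weighted=weighted))
            want = betweenness_oracle(net, weighted=weighted)
            for node in want:
                assert got[node] == pytest.approx(want[node], abs=1e-9)

    def test_oracle_refuses_large_graphs(self):
        net = make_net(nx.path_graph(9))
        with pytest.raises(ValueError, match="8 nodes"):
            betweenness_oracle(net)


class TestEigenvector:
    def test_complete_graph_is_uniform(self):
        G = nx.complete_graph(5)
        nx.set_edge_attributes(G, 1.0, "weight")
        vals = as_dict(eigenvector(make_net(G, "FIGHT")), "normalised")
        assert all(v == pytest.approx(1.0) for v in vals.values())

    def test_star_centre_dominates_equal_leaves(self):
        G = nx.star_graph(4)
        nx.set_edge_attributes(G, 1.0, "weight")
        vals = as_dict(eigenvector(make_net(G, "FIGHT")), "normalised")
        assert vals[0] == pytest.approx(1.0)
        leaves = [vals[v] for v in range(1, 5)]
        assert all(l == pytest.approx(leaves[0]) for l in leaves)
        assert leaves[0] < 1.0

    def test_empty_network_is_all_zero(self):
        G = nx.Graph()
        G.add_nodes_from("abc")
        vals = as_dict(eigenvector(make_net(G, "FIGHT")))
        assert set(vals.values()) == {0.0}

    def test_residual_small_on_random_weighted_graphs(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            net = random_net(rng, directed=False, weighted=True, n=10)
            assert eigenvector_residual(net) < 1e-8

    def test_directed_win_network_uses_undirected_projection(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=3.0)
        G.add_edge("b", "a", weight=1.0)
        G.add_edge("b", "c", weight=4.0)
        vals = as_dict(eigenvector(make_net(G, "WIN")), "normalised")
        assert vals["b"] == pytest.approx(1.0)
        assert vals["a"] == pytest.approx(vals["c"])  # 4 vs 4 after projection


class TestRedundancyScreen:
    @staticmethod
    def table(metric, counterpart, x, y, net_type="ALL"):
        rows = []
        for i, (a, b) in enumerate(zip(x, y)):
            rows.append({"pig": f"p{i}", "net_type": net_type, "metric": metric,
                         "normalised": a})
            rows.append({"pig": f"p{i}", "net_type": net_type,
                         "metric": counterpart, "normalised": b})
        return pd.DataFrame(rows)

    def test_perfect_linear_relation_is_redundant(self):
        x = [1.0, 2.0, 5.0, 9.0]
        out = redundancy_screen(self.table("w_degree", "degree", [2 * v for v in x], x))
        assert out.iloc[0]["redundant"] and out.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_vectors_are_not_redundant(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=200), rng.normal(size=200)
        out = redundancy_screen(self.table("w_betweenness", "betweenness", x, y))
        assert abs(out.iloc[0]["r"]) < 0.8 and not out.iloc[0]["redundant"]

    def test_exactly_point_eight_is_not_redundant(self):
        # x and z orthogonal with equal variance; y = 4x + 3z gives r = 0.8
        x = np.array([3.0, 1.0, -1.0, -3.0])
        z = np.array([1.0, -3.0, 3.0, -1.0])
        y = 4 * x + 3 * z
        out = redundancy_screen(self.table("w_degree", "degree", y, x))
        assert out.iloc[0]["r"] == pytest.approx(0.8, abs=1e-12)
        assert not out.iloc[0]["redundant"]

    def test_zero_variance_is_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = redundancy_screen(
                self.table("w_degree", "degree", [1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
            )
        assert len(out) == 0


def test_centrality_table_covers_expected_metrics(small_study):
    from pignet.pipeline import analyse_networks

    table = analyse_networks(small_study.roster, small_study.events)
    by_type = table.groupby("net_type")["metric"].agg(set)
    assert "eigenvector" in by_type["FIGHT"] and "eigenvector" in by_type["WIN"]
    assert "eigenvector" not in by_type.get("ALL", set())
    assert {"indegree", "outdegree"} <= by_type["ALL"]
    assert {"indegree", "outdegree"}.isdisjoint(by_type["FIGHT"])
    # unweighted normalised degree is a proportion of potential opponents
    deg = table[(table.metric == "degree")]
    assert ((deg.normalised >= 0) & (deg.normalised <= 1)).all()
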