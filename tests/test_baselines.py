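"""Baseline rankers: centralities, restart walk, t-test, randomization."""

import heapq
import itertools
import math

import numpy as np
import pytest

from flowtarget import (
    InteractionRecord,
    WeightedNetwork,
    betweenness_rank,
    build_weighted_network,
    closeness_rank,
    degree_rank,
    entropy_rank,
    log_trend_fit,
    randomize_directions,
    rwr_rank,
    ttest_rank,
)
from flowtarget.baselines import _link_degrees, rwr_scores

from conftest import make_matrix


def star(n_leaves=5, cap=1.0):
    net = WeightedNetwork()
    for i in range(n_leaves):
        net.add_arc("hub", f"leaf{i}", cap, "ppi")
        net.add_arc(f"leaf{i}", "hub", cap, "ppi")
    return net


def random_weighted_net(rng, n=8, p=0.5):
    net = WeightedNetwork()
    names = [f"n{i}" for i in range(n)]
    for u, v in itertools.permutations(names, 2):
        if rng.random() < p:
            net.add_arc(u, v, float(rng.uniform(0.1, 2.0)), "regulatory")
    return net


class TestDegreeRank:
    def test_star_center_first(self):
        net = star()
        order = degree_rank(net, {"hub", "leaf0", "leaf3"})
        assert order[0] == "hub"

    def test_fixture_degrees_counted_by_hand(self, fig2):
        deg = _link_degrees(fig2.network)
        assert deg["G1"] == 3  # G1→G6, G1→G3, G4→G1
        assert deg["G5"] == 1  # G5→G7
        order = degree_rank(fig2.network, {"G1", "G5"})
        assert order == ["G1", "G5"]

    def test_input_order_invariance(self, fig2):
        assert degree_rank(fig2.network, {"G1", "G2", "G5"}) == degree_rank(
            fig2.network, {"G5", "G2", "G1"}
        )


class TestEntropyRank:
    def test_single_neighbor_entropy_zero(self):
        net = WeightedNetwork()
        net.add_arc("A", "B", 1.0, "regulatory")
        order = entropy_rank(net, {"A", "B"})
        assert order == ["A", "B"]  # both entropy 0, lexicographic

    def test_uniform_neighbors_give_log2_m(self):
        # hub with m leaves of equal degree: H(hub) = log2 m
        net = star(n_leaves=8)
        deg = _link_degrees(net)
        total = sum(deg[f"leaf{i}"] for i in range(8))
        h = -sum(
            (deg[f"leaf{i}"] / total) * math.log2(deg[f"leaf{i}"] / total)
            for i in range(8)
        )
        assert h == pytest.approx(math.log2(8))
        assert entropy_rank(net, {"hub", "leaf0"})[0] == "hub"

    def test_matches_brute_force_sum(self, rng):
        net = random_weighted_net(rng)
        deg = _link_degrees(net)
        nbrs = {v: set() for v in net.graph.nodes}
        for u, v in net.graph.edges():
            nbrs[u].add(v)
            nbrs[v].add(u)
        scores = {}
        for node in net.graph.nodes:
            total = sum(deg[j] for j in nbrs[node])
            scores[node] = -sum(
                (deg[j] / total) * math.log2(deg[j] / total) for j in nbrs[node]
            ) if total else 0.0
        expected = sorted(net.graph.nodes, key=lambda c: (-scores[c], c))
        assert entropy_rank(net, set(net.graph.nodes)) == expected


def dijkstra(net, src):
    dist = {src: 0.0}
    heap = [(0.0, src)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, float("inf")):
            continue
        for _, v, data in net.graph.out_edges(u, data=True):
            if data["capacity"] <= 0:
                continue
            nd = d + 1.0 / data["capacity"]
            if nd < dist.get(v, float("inf")) - 1e-15:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


class TestPathCentralities:
    def test_path_graph_middle_node_most_between(self):
        net = WeightedNetwork()
        for a, b in [("A", "B"), ("B", "C")]:
            net.add_arc(a, b, 1.0, "ppi")
            net.add_arc(b, a, 1.0, "ppi")
        assert betweenness_rank(net, {"A", "B", "C"})[0] == "B"

    def test_complete_graph_equal_weights_all_zero_betweenness(self):
        net = random_weighted_net(np.random.default_rng(0), n=4, p=1.1)
        for u, v in net.graph.edges():
            net.graph[u][v]["capacity"] = 1.0
        # every pair is adjacent: no node lies strictly between any other two
        order = betweenness_rank(net, set(net.graph.nodes))
        assert order == sorted(net.graph.nodes)  # all ties → lexicographic

    def test_closeness_matches_brute_force_dijkstra(self, rng):
        net = random_weighted_net(rng)
        scores = {}
        for node in net.graph.nodes:
            dist = dijkstra(net, node)
            reach = {k: v for k, v in dist.items() if k != node and v < float("inf")}
            scores[node] = (len(reach) / sum(reach.values())) if reach else 0.0
        expected = sorted(net.graph.nodes, key=lambda c: (-round(scores[c], 12), c))
        got = closeness_rank(net, set(net.graph.nodes))
        got_scores = [round(scores[c], 6) for c in got]
        assert got_scores == sorted(got_scores, reverse=True)
        assert got == expected

    def test_path_endpoint_less_close_than_center(self):
        net = WeightedNetwork()
        for a, b in [("A", "B"), ("B", "C")]:
            net.add_arc(a, b, 1.0, "ppi")
            net.add_arc(b, a, 1.0, "ppi")
        assert closeness_rank(net, {"A", "B", "C"})[0] == "B"


class TestRandomWalkRestart:
    def test_self_disease_score_at_least_alpha(self, fig2):
        score = rwr_scores(fig2.network, "G1", {"G1"}, alpha=0.3)
        assert score >= 0.3 - 1e-9

    def test_two_state_chain_closed_form(self):
        net = WeightedNetwork()
        net.add_arc("A", "B", 1.0, "regulatory")
        # stationary: x_A = 0.3 + 0.7 x_B (dangling), x_B = 0.7 x_A
        assert rwr_scores(net, "A", {"B"}, alpha=0.3) == pytest.approx(
            0.7 * 0.3 / (1 - 0.49), abs=1e-8
        )

    def test_ranking_prefers_network_proximity(self, fig2):
        order = rwr_rank(fig2.network, {"G1", "G4"}, {"G6", "G7"})
        assert order[0] == "G1"  # G4 is one hop further from the disease genes

    def test_invalid_alpha_rejected(self, fig2):
        with pytest.raises(ValueError):
            rwr_scores(fig2.network, "G1", {"G6"}, alpha=1.5)


class TestTTestRank:
    def test_flat_gene_ranks_last(self, rng):
        vals = rng.normal(size=(3, 10))
        vals[0, :5] += 4.0       # strongly differential
        vals[2] = 1.0            # identical groups → |t| = 0
        m = make_matrix(vals, cancer=5, normal=5)
        order = ttest_rank(m, {"g0", "g1", "g2"})
        assert order[0] == "g0" and order[-1] == "g2"

    def test_matches_independent_sort(self, rng):
        from flowtarget import ttest_statistic

        m = make_matrix(rng.normal(size=(6, 12)), cancer=7, normal=5)
        cands = set(m.gene_ids)
        expected = sorted(cands, key=lambda g: (-abs(ttest_statistic(m, g)), g))
        assert ttest_rank(m, cands) == expected


class TestRandomizeDirections:
    def test_regulatory_only_network_unchanged(self, fig2):
        out = randomize_directions(fig2.network, seed=1)
        assert sorted(out.arcs()) == sorted(fig2.network.arcs())

    def test_same_seed_reproducible(self):
        net = star(6)
        a = randomize_directions(net, seed=7)
        b = randomize_directions(net, seed=7)
        assert sorted(a.arcs()) == sorted(b.arcs())

    def test_each_ppi_pair_collapses_to_one_arc(self):
        net = star(6)
        out = randomize_directions(net, seed=3)
        assert out.graph.number_of_edges() == 6
        for u, v in net.ppi_pairs():
            assert out.graph.has_edge(u, v) != out.graph.has_edge(v, u)
            cap = out.graph[u][v] if out.graph.has_edge(u, v) else out.graph[v][u]
            assert cap["capacity"] == net.graph[u][v]["capacity"]


class TestLogTrendFit:
    def test_exact_recovery(self):
        ranks = list(range(1, 30))
        values = [-2.0 * math.log(x) + 5.0 for x in ranks]
        a, b = log_trend_fit(ranks, values)
        assert a == pytest.approx(-2.0, abs=1e-9)
        assert b == pytest.approx(5.0, abs=1e-9)

    def test_constant_values_give_zero_slope(self):
        a, b = log_trend_fit([1, 2, 3, 4], [3.0, 3.0, 3.0, 3.0])
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(3.0, abs=1e-12)

    def test_matches_normal_equations_on_noisy_points(self, rng):
        ranks = list(range(1, 50))
        values = [-2.9 * math.log(x) + 15.0 + rng.normal(0, 0.5) for x in ranks]
        a, b = log_trend_fit(ranks, values)
        X = np.column_stack([np.log(ranks), np.ones(len(ranks))])
        beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(values))
        assert a == pytest.approx(beta[0], abs=1e-9)
        assert b == pytest.approx(beta[1], abs=1e-9)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            log_trend_fit([1], [2.0])


class TestComparisonFairness:
    def test_all_rankers_return_total_order_over_candidates(self, rng):
        from flowtarget import simulate_dataset
        from flowtarget.expression import filter_genes_by_missingness, knn_impute
        from flowtarget.network import map_and_deduplicate

        ds = simulate_dataset(seed=5, missing_rate=0.0)
        net = build_weighted_network(map_and_deduplicate(ds.records), ds.matrix)
        cands = ds.candidates
        for order in (
            degree_rank(net, cands),
            entropy_rank(net, cands),
            betweenness_rank(net, cands),
            closeness_rank(net, cands),
            rwr_rank(net, cands, ds.disease),
            ttest_rank(ds.matrix, cands),
        ):
            assert sorted(order) == sorted(cands)
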