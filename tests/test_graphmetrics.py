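"""Graph metrics vs worked examples, brute-force oracles, and networkx."""

import networkx as nx
import numpy as np
import pytest

from cognet.community import Partition, louvain, modularity
from cognet.graph import CognitiveGraph
from cognet.metrics import (
    betweenness,
    clustering_coefficient,
    global_efficiency,
    global_efficiency_node,
    hubs,
    local_efficiency,
    node_density,
    node_metrics,
    whole_density,
)
from conftest import graph_from_edges, neighbor_example_graph
from oracles import (
    betweenness_oracle,
    clustering_oracle,
    global_efficiency_oracle,
    local_efficiency_oracle,
    max_modularity_oracle,
    modularity_oracle,
    random_binary_graph,
)


def complete_graph(n):
    return graph_from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


class TestWorkedExamples:
    @pytest.mark.parametrize(
        "connected_pairs,expected", [(0, 0.0), (1, 1 / 3), (3, 1.0)]
    )
    def test_clustering_of_focal_node(self, connected_pairs, expected):
        # three neighbors with 0, 1 or all 3 pairs mutually connected
        g = neighbor_example_graph(connected_pairs)
        assert clustering_coefficient(g)[0] == pytest.approx(expected)

    def test_path_betweenness(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        assert betweenness(g).tolist() == [0.0, 1.0, 0.0]

    def test_star_betweenness_counts_leaf_pairs(self, star_graph):
        bc = betweenness(star_graph)
        assert bc[0] == 6.0  # C(4, 2) leaf pairs route through the center
        assert np.all(bc[1:] == 0.0)

    def test_path4_global_efficiency_closed_form(self, path_graph):
        eg = global_efficiency_node(path_graph)
        assert eg[0] == pytest.approx((1 + 1 / 2 + 1 / 3) / 3)  # 11/18

    def test_star_center_local_efficiency_zero(self, star_graph):
        assert local_efficiency(star_graph)[0] == 0.0

    def test_triangle_local_efficiency_one(self):
        g = complete_graph(3)
        assert np.all(local_efficiency(g) == 1.0)

    def test_isolated_node_zero_efficiency(self):
        g = graph_from_edges(3, [(0, 1)])
        assert global_efficiency_node(g)[2] == 0.0


class TestOracleEquivalence:
    def test_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            adj = random_binary_graph(rng, n, float(rng.uniform(0.1, 0.9)))
            assert np.allclose(betweenness(adj), betweenness_oracle(adj), atol=1e-12)
            assert np.allclose(clustering_coefficient(adj), clustering_oracle(adj))
            assert np.allclose(
                global_efficiency_node(adj), global_efficiency_oracle(adj)
            )
            assert np.allclose(local_efficiency(adj), local_efficiency_oracle(adj))

    def test_matches_networkx_conventions(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            adj = random_binary_graph(rng, n, 0.4)
            g = nx.from_numpy_array(adj)
            assert np.allclose(
                betweenness(adj),
                list(nx.betweenness_centrality(g, normalized=False).values()),
            )
            assert np.allclose(
                clustering_coefficient(adj), list(nx.clustering(g).values())
            )
            if nx.is_connected(g):
                assert global_efficiency(adj) == pytest.approx(
                    nx.global_efficiency(g)
                )


class TestInvariants:
    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_graph_extremes(self, n):
        g = complete_graph(n)
        assert np.all(betweenness(g) == 0.0)
        assert np.all(clustering_coefficient(g) == 1.0)
        assert np.all(local_efficiency(g) == 1.0)
        assert np.all(global_efficiency_node(g) == 1.0)
        assert whole_density(g) == 1.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        adj = random_binary_graph(rng, 8, 0.4)
        perm = rng.permutation(8)
        padj = adj[np.ix_(perm, perm)]
        for fn in (
            betweenness,
            clustering_coefficient,
            local_efficiency,
            global_efficiency_node,
            node_density,
        ):
            assert np.allclose(fn(adj)[perm], fn(padj), atol=1e-12)

    def test_adding_edge_never_decreases_efficiency_or_density(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            adj = random_binary_graph(rng, 7, 0.3)
            empty = np.argwhere(np.triu(adj == 0, k=1))
            if not len(empty):
                continue
            i, j = empty[rng.integers(len(empty))]
            denser = adj.copy()
            denser[i, j] = denser[j, i] = 1
            assert np.all(
                global_efficiency_node(denser) >= global_efficiency_node(adj) - 1e-12
            )
            assert np.all(node_density(denser) >= node_density(adj))

    def test_mean_node_density_equals_whole_density(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            adj = random_binary_graph(rng, 9, 0.5)
            assert node_density(adj).mean() == pytest.approx(whole_density(adj))

    def test_empty_graph_density_zero(self):
        adj = np.zeros((5, 5), dtype=int)
        assert whole_density(adj) == 0.0
        assert np.all(node_density(adj) == 0.0)


class TestHubs:
    def test_no_spread_no_hubs(self):
        assert not hubs([2.0, 2.0, 2.0]).any()

    def test_single_outlier_is_hub(self):
        # mean 2, sample SD ~4.47 -> threshold ~8.7: only the 10 qualifies
        flags = hubs([0.0, 0.0, 0.0, 0.0, 10.0])
        assert flags.tolist() == [False, False, False, False, True]

    def test_star_center_is_hub(self, star_graph):
        assert hubs(betweenness(star_graph)).tolist() == [True] + [False] * 4


class TestLouvain:
    def test_two_disjoint_triangles(self):
        g = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = louvain(g, seed=0)
        assert part.modularity_Q == pytest.approx(0.5)
        assert set(part.communities()) == {
            frozenset({"n0", "n1", "n2"}),
            frozenset({"n3", "n4", "n5"}),
        }

    def test_edgeless_graph_all_singletons(self):
        g = CognitiveGraph(("a", "b", "c"), np.zeros((3, 3), dtype=int))
        part = louvain(g, seed=0)
        assert part.n_communities == 3
        assert part.modularity_Q == 0.0

    def test_isolated_node_is_singleton(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (0, 2)])
        part = louvain(g, seed=1)
        assert {"n3"} in [set(c) for c in part.communities()]

    def test_reported_q_recomputable_independently(self):
        rng = np.random.default_rng(3)
        for seed in range(15):
            adj = random_binary_graph(rng, 10, 0.4)
            g = CognitiveGraph(tuple(f"n{i}" for i in range(10)), adj)
            part = louvain(g, seed=seed)
            labels = part.labels(g.nodes)
            assert part.modularity_Q == pytest.approx(
                modularity_oracle(adj, labels), abs=1e-12
            )
            # and against networkx's modularity of the same grouping
            q_nx = nx.community.modularity(
                nx.from_numpy_array(adj) if adj.sum() else nx.empty_graph(10),
                [
                    {i for i in range(10) if labels[i] == c}
                    for c in sorted(set(labels))
                ],
            ) if adj.sum() else 0.0
            assert part.modularity_Q == pytest.approx(q_nx, abs=1e-12)

    def test_never_exceeds_exhaustive_maximum(self):
        rng = np.random.default_rng(29)
        attained = total = 0
        for seed in range(30):
            n = int(rng.integers(4, 9))
            adj = random_binary_graph(rng, n, float(rng.uniform(0.2, 0.8)))
            g = CognitiveGraph(tuple(f"n{i}" for i in range(n)), adj)
            part = louvain(g, seed=seed)
            q_max = max_modularity_oracle(adj)
            assert part.modularity_Q <= q_max + 1e-9
            total += 1
            attained += abs(part.modularity_Q - q_max) < 1e-9
        assert attained / total >= 0.8

    def test_planted_two_block_recovery(self):
        rng = np.random.default_rng(31)
        planted = frozenset({f"n{i}" for i in range(5)})
        hits = 0
        for seed in range(50):
            adj = np.zeros((10, 10), dtype=int)
            for i in range(10):
                for j in range(i + 1, 10):
                    same = (i < 5) == (j < 5)
                    if rng.random() < (0.9 if same else 0.05):
                        adj[i, j] = adj[j, i] = 1
            g = CognitiveGraph(tuple(f"n{i}" for i in range(10)), adj)
            part = louvain(g, seed=seed)
            comms = set(part.communities())
            if planted in comms and len(comms) == 2:
                hits += 1
        assert hits >= 45  # >= 90% of 50 seeds

    def test_restarts_never_worsen_q(self):
        rng = np.random.default_rng(37)
        for seed in range(10):
            adj = random_binary_graph(rng, 12, 0.3)
            g = CognitiveGraph(tuple(f"n{i}" for i in range(12)), adj)
            q1 = louvain(g, seed=seed, restarts=1).modularity_Q
            q5 = louvain(g, seed=seed, restarts=5).modularity_Q
            assert q5 >= q1 - 1e-12


class TestNodeMetricsTable:
    def test_table_contents(self, star_graph):
        frame = node_metrics(star_graph, seed=0)
        assert list(frame.index) == list(star_graph.nodes)
        assert frame.loc["n0", "degree"] == 4
        assert frame.loc["n0", "betweenness"] == 6.0
        assert frame.loc["n0", "clustering"] == 0.0  # leaves unconnected
        assert frame.loc["n1", "clustering"] == 0.0  # degree < 2
        assert frame.loc["n0", "hub"]
        assert frame["community"].nunique() >= 1

    def test_density_column_is_degree_over_n_minus_one(self, path_graph):
        frame = node_metrics(path_graph, seed=0)
        assert np.allclose(frame["density"], frame["degree"] / 3)
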