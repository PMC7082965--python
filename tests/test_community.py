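import networkx as nx
import numpy as np
import pytest

from helpers import (
    all_set_partitions,
    brute_modularity,
    brute_modularity_density,
    random_labels,
    random_weighted_graph,
)

from coexnet import (
    UNASSIGNED,
    Partition,
    finalize_partition,
    maximize,
    modularity,
    modularity_density,
    rand_index,
)
from coexnet.errors import ValidationError


class TestModularity:
    def test_one_community_is_zero(self, two_triangles):
        part = Partition({v: 1 for v in two_triangles})
        assert modularity(two_triangles, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangle_components_give_half(self, two_triangles):
        part = Partition({0: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2})
        assert modularity(two_triangles, part) == pytest.approx(0.5, abs=1e-12)

    def test_all_singletons_negative(self, two_triangles):
        part = Partition({v: v + 1 for v in two_triangles})
        assert modularity(two_triangles, part) < 0

    def test_unassigned_scored_as_singletons(self, two_triangles):
        explicit = Partition({0: 1, 1: 1, 2: 1, 3: 2, 4: 3, 5: 4})
        implicit = Partition({0: 1, 1: 1, 2: 1, 3: UNASSIGNED, 4: UNASSIGNED,
                              5: UNASSIGNED})
        assert modularity(two_triangles, implicit) == pytest.approx(
            modularity(two_triangles, explicit), abs=1e-12
        )

    def test_missing_node_rejected(self, two_triangles):
        with pytest.raises(ValidationError):
            modularity(two_triangles, Partition({0: 1}))

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            graph = random_weighted_graph(rng, int(rng.integers(5, 15)), 0.4)
            labels = random_labels(rng, graph.nodes)
            mine = modularity(graph, Partition(labels))
            communities = [
                {u for u in graph.nodes if labels[u] == c}
                for c in set(labels.values())
            ]
            theirs = nx.community.modularity(graph, communities, weight="weight")
            assert mine == pytest.approx(theirs, abs=1e-10)


class TestModularityDensity:
    def test_two_triangle_components_give_half(self, two_triangles):
        part = Partition({0: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2})
        assert modularity_density(two_triangles, part) == pytest.approx(0.5, abs=1e-12)

    def test_single_clique_community_is_zero(self):
        clique = nx.complete_graph(5)
        part = Partition({v: 1 for v in clique})
        assert modularity_density(clique, part) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            graph = random_weighted_graph(rng, int(rng.integers(4, 9)), 0.5)
            labels = random_labels(rng, graph.nodes)
            assert modularity_density(graph, Partition(labels)) == pytest.approx(
                brute_modularity_density(graph, labels), abs=1e-12
            )

    def test_matches_brute_force_over_all_partitions(self):
        rng = np.random.default_rng(2)
        graph = random_weighted_graph(rng, 6, 0.6)
        nodes = list(graph.nodes)
        for blocks in all_set_partitions(nodes):
            labels = {u: i + 1 for i, block in enumerate(blocks) for u in block}
            part = Partition(labels)
            assert modularity(graph, part) == pytest.approx(
                brute_modularity(graph, labels), abs=1e-12
            )
            assert modularity_density(graph, part) == pytest.approx(
                brute_modularity_density(graph, labels), abs=1e-12
            )


class TestMaximize:
    def test_two_triangles_recovered_optimally(self, two_triangles):
        for objective in ("Q", "Qds"):
            part, score = maximize(two_triangles, objective=objective, seed=0)
            assert part.n_modules == 2
            assert set(part.modules().values()) == {
                frozenset({0, 1, 2}), frozenset({3, 4, 5})
            }
            assert score.q == pytest.approx(0.5, abs=1e-12)

    def test_single_edge_merges_both_nodes(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", weight=1.0)
        part, score = maximize(graph, objective="Q", seed=0)
        assert part.assignment == {"a": 1, "b": 1}
        assert score.q == pytest.approx(0.0, abs=1e-12)

    def test_empty_and_edgeless_graphs_rejected(self):
        with pytest.raises(ValueError):
            maximize(nx.Graph())
        lonely = nx.Graph()
        lonely.add_nodes_from(["a", "b"])
        with pytest.raises(ValueError):
            maximize(lonely)

    def test_isolated_nodes_unassigned(self, two_triangles):
        graph = two_triangles.copy()
        graph.add_nodes_from(["iso1", "iso2"])
        part, _ = maximize(graph, seed=0)
        assert part.unassigned() == {"iso1", "iso2"}
        assert part.n_modules == 2

    @pytest.mark.parametrize("objective", ["Q", "Qds"])
    def test_recovers_exhaustive_optimum_on_small_graphs(self, objective):
        """The returned partition attains the true global optimum (<=7 nodes)."""
        rng = np.random.default_rng(7)
        fn = modularity if objective == "Q" else modularity_density
        for _ in range(12):
            graph = random_weighted_graph(rng, int(rng.integers(4, 8)), 0.55)
            nodes = [u for u in graph.nodes if graph.degree(u) > 0]
            isolated = [u for u in graph.nodes if graph.degree(u) == 0]
            best = -np.inf
            for blocks in all_set_partitions(nodes):
                labels = {u: i + 1 for i, b in enumerate(blocks) for u in b}
                labels.update({u: UNASSIGNED for u in isolated})
                best = max(best, fn(graph, Partition(labels)))
            _, score = maximize(graph, objective=objective, seed=0)
            achieved = score.q if objective == "Q" else score.qds
            assert achieved == pytest.approx(best, abs=1e-9)

    def test_never_worse_than_trivial_partitions(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            graph = random_weighted_graph(rng, 20, 0.25)
            for objective, fn in (("Q", modularity), ("Qds", modularity_density)):
                _, score = maximize(graph, objective=objective, seed=0)
                achieved = score.q if objective == "Q" else score.qds
                one = Partition({v: 1 for v in graph})
                singles = Partition({v: i + 1 for i, v in enumerate(graph)})
                assert achieved >= fn(graph, one) - 1e-12
                assert achieved >= fn(graph, singles) - 1e-12

    def test_deterministic_given_seed(self, planted):
        p1, s1 = maximize(planted["graph"], seed=3)
        p2, s2 = maximize(planted["graph"], seed=3)
        assert p1.assignment == p2.assignment
        assert s1.q == s2.q

    def test_relabeling_equivariance(self, planted):
        graph = planted["graph"]
        mapping = {v: f"x_{v}" for v in graph.nodes}
        relabeled = nx.relabel_nodes(graph, mapping)
        p1, _ = maximize(graph, seed=0)
        p2, _ = maximize(relabeled, seed=0)
        renamed = Partition({mapping[v]: lab for v, lab in p1.assignment.items()})
        assert rand_index(renamed, p2).ri == pytest.approx(1.0)

    def test_no_community_spans_components(self):
        rng = np.random.default_rng(4)
        g1 = random_weighted_graph(rng, 10, 0.5)
        g2 = nx.relabel_nodes(random_weighted_graph(rng, 10, 0.5),
                              {i: 100 + i for i in range(10)})
        graph = nx.union(g1, g2)
        part, _ = maximize(graph, seed=0)
        for members in part.modules().values():
            assert {v < 100 for v in members} in ({True}, {False})

    def test_planted_modules_recovered(self, planted):
        part, score = maximize(planted["graph"], objective="Qds", seed=0)
        assert part.n_modules == 5
        assert rand_index(part, planted["truth"]).ri >= 0.95
        assert score.q > 0.5


class TestFinalizePartition:
    def test_isolated_nodes_demoted(self, two_triangles):
        graph = two_triangles.copy()
        graph.add_nodes_from(["i1", "i2", "i3"])
        part = Partition({v: 1 for v in graph})
        final = finalize_partition(part, graph)
        assert final.unassigned() == {"i1", "i2", "i3"}

    def test_identity_without_min_size(self, two_triangles):
        part = Partition({0: 2, 1: 2, 2: 2, 3: 1, 4: 1, 5: 1})
        final = finalize_partition(part, two_triangles, min_module_size=1)
        assert final.n_modules == 2
        assert final.n_unassigned == 0

    def test_small_modules_dissolved_and_labels_by_size(self):
        graph = nx.Graph()
        graph.add_edges_from([("a", "b"), ("b", "c"), ("d", "e"), ("f", "g"),
                              ("g", "h"), ("h", "f"), ("f", "i")])
        part = Partition({"a": 5, "b": 5, "c": 5, "d": 9, "e": 9,
                          "f": 2, "g": 2, "h": 2, "i": 2})
        final = finalize_partition(part, graph, min_module_size=3)
        assert final.n_modules == 2
        assert final.assignment["f"] == 1  # largest module first
        assert final.assignment["a"] == 2
        assert final.unassigned() == {"d", "e"}
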