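"""Dual-graph transform, strongest-path search and epsilon subnetworks."""

import math

import networkx as nx
import pytest

from strongpaths import (
    ConfidenceNetwork,
    build_dual,
    dual_weight,
    epsilon_subnetwork,
    strongest_path,
)
from strongpaths.errors import InputError
from strongpaths.fixtures import brute_force_strongest, random_network


class TestDualWeight:
    def test_values(self):
        assert dual_weight(1.0, 1.0) == 0.0
        assert dual_weight(1.0, 0.95) == pytest.approx(-math.log(0.95), abs=1e-12)
        assert dual_weight(0.5, 0.95) == pytest.approx(
            -(math.log(0.95) + math.log(0.5)), abs=1e-12
        )

    @pytest.mark.parametrize("p,d", [(0.0, 0.95), (1.2, 0.95), (0.5, 0.0), (0.5, 1.1)])
    def test_domain_errors(self, p, d):
        with pytest.raises(InputError):
            dual_weight(p, d)


class TestBuildDual:
    def test_super_edges_are_zero_weight(self):
        net = ConfidenceNetwork(
            directed=True, labels=["a1", "a2", "b"],
            edges={(0, 2): 0.8, (1, 2): 0.8},
        )
        dual = build_dual(net, {0, 1}, {2}, d=0.95)
        super_out = dual.forward[dual.sigma]
        assert len(super_out) == 2
        assert all(w == 0.0 and hop == 0 for _, w, hop in super_out)
        real = [e for e in dual.forward[0] if e[0] == 2]
        assert real[0][1] == pytest.approx(-(math.log(0.95) + math.log(0.8)))

    def test_input_validation(self, triangle):
        with pytest.raises(InputError, match="disjoint"):
            build_dual(triangle, {0, 1}, {1, 2})
        with pytest.raises(InputError, match="non-empty"):
            build_dual(triangle, set(), {2})
        with pytest.raises(InputError, match="not in network"):
            build_dual(triangle, {0}, {7})


class TestStrongestPath:
    def test_length_penalty_keeps_the_better_product(self, triangle):
        r = strongest_path(triangle, {0}, {2}, d=0.95)
        assert r.labels == ("A", "B", "C")
        assert r.product == pytest.approx(0.81)
        assert r.penalized_score == pytest.approx(0.731025)

    def test_length_penalty_flips_to_the_direct_edge(self):
        net = ConfidenceNetwork(
            directed=True, labels=["A", "B", "C"],
            edges={(0, 1): 0.9, (1, 2): 0.9, (0, 2): 0.78},
        )
        r = strongest_path(net, {0}, {2}, d=0.95)
        assert r.labels == ("A", "C")
        assert r.penalized_score == pytest.approx(0.741)

    def test_no_path_is_a_first_class_result(self):
        net = ConfidenceNetwork(
            directed=True, labels=["A", "B"], edges={(1, 0): 0.9}
        )
        r = strongest_path(net, {0}, {1})
        assert not r.exists
        assert r.nodes == ()

    def test_log_consistency(self, triangle):
        r = strongest_path(triangle, {0}, {2})
        assert r.dual_length + math.log(r.penalized_score) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_unit_weights_reduce_to_bfs(self):
        for seed in range(20):
            net = random_network(9, 0.35, weight_range=(1.0, 1.0), seed=seed)
            g = nx.Graph()
            g.add_nodes_from(range(9))
            g.add_edges_from(net.edges)
            r = strongest_path(net, {0}, {8}, d=0.95)
            try:
                hops = nx.shortest_path_length(g, 0, 8)
            except nx.NetworkXNoPath:
                assert not r.exists
                continue
            assert r.edge_count == hops

    def test_deterministic_label_tie_break(self):
        # two disjoint 2-hop routes with identical products
        net = ConfidenceNetwork(
            directed=True, labels=["A", "Z", "M", "B"],
            edges={(0, 1): 0.8, (1, 3): 0.8, (0, 2): 0.8, (2, 3): 0.8},
        )
        r = strongest_path(net, {0}, {3})
        assert r.labels == ("A", "M", "B")

    def test_matches_brute_force_on_random_graphs(self):
        for seed in range(40):
            directed = bool(seed % 2)
            d = [1.0, 0.95, 0.8][seed % 3]
            net = random_network(7, 0.4, directed=directed, seed=seed)
            best, argmax = brute_force_strongest(net, {0}, {6}, d)
            r = strongest_path(net, {0}, {6}, d=d)
            if best is None:
                assert not r.exists
            else:
                assert r.penalized_score == pytest.approx(best, abs=1e-9)
                assert r.nodes in argmax


class TestEpsilonSubnetwork:
    def test_diamond_grows_with_epsilon(self, diamond):
        sub = epsilon_subnetwork(diamond, {0}, {3}, epsilon=0.1)
        assert {diamond.labels[v] for v in sub.nodes} == {"A", "X", "B"}
        sub = epsilon_subnetwork(diamond, {0}, {3}, epsilon=0.3)
        assert {diamond.labels[v] for v in sub.nodes} == {"A", "X", "Y", "B"}
        # dual lengths of the two routes: -2(ln .95 + ln .9) and -2(ln .95 + ln .8)
        assert sub.w_star == pytest.approx(0.3133076, abs=1e-6)
        assert sub.a[2] + sub.b[2] == pytest.approx(0.5488737, abs=1e-6)

    def test_epsilon_zero_is_the_optimal_node_set(self, diamond):
        sub = epsilon_subnetwork(diamond, {0}, {3}, epsilon=0.0)
        best = strongest_path(diamond, {0}, {3})
        assert set(best.nodes) <= set(sub.nodes)
        assert {diamond.labels[v] for v in sub.nodes} == {"A", "X", "B"}

    def test_monotone_in_epsilon(self):
        net = random_network(9, 0.4, seed=11)
        sizes = []
        prev: frozenset = frozenset()
        for eps in (0.0, 0.1, 0.5, 2.0):
            sub = epsilon_subnetwork(net, {0}, {8}, epsilon=eps)
            assert prev <= sub.nodes
            prev = sub.nodes
            sizes.append(len(sub.nodes))
        assert sizes == sorted(sizes)

    def test_sparse_edges_subset_of_dense(self, diamond):
        extra = dict(diamond.edges)
        extra[(1, 2)] = 0.9  # X->Y chord: in the induced set, on no eps-path
        net = ConfidenceNetwork(directed=True, labels=diamond.labels, edges=extra)
        # eps=0.25 keeps Y (a+b ~ 0.549 <= 0.563) but not the chord (~ 0.588)
        dense = epsilon_subnetwork(net, {0}, {3}, epsilon=0.25, sparse=False)
        sparse = epsilon_subnetwork(net, {0}, {3}, epsilon=0.25, sparse=True)
        assert sparse.nodes == dense.nodes
        assert set(sparse.edges) < set(dense.edges)
        assert (1, 2) in dense.edges and (1, 2) not in sparse.edges

    def test_layers_are_bfs_hops_from_sources(self, diamond):
        sub = epsilon_subnetwork(diamond, {0}, {3}, epsilon=0.3)
        assert sub.layers[0] == 0
        assert sub.layers[1] == sub.layers[2] == 1
        assert sub.layers[3] == 2

    def test_negative_epsilon_rejected(self, diamond):
        with pytest.raises(InputError):
            epsilon_subnetwork(diamond, {0}, {3}, epsilon=-0.1)

    def test_no_path_subnetwork_is_empty(self):
        net = ConfidenceNetwork(directed=True, labels=["A", "B"], edges={(1, 0): 0.9})
        sub = epsilon_subnetwork(net, {0}, {1}, epsilon=1.0)
        assert not sub.exists
        assert sub.nodes == frozenset()
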