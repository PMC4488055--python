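"""Network assembly, subnetworks, neighbors, paths, hubs, and modules."""

import math

import networkx as nx
import pytest

from mircircuit.network_core import (
    activated_predicate,
    build_network,
    decompose_modules,
    degree_rank,
    first_neighbors,
    induced_subnetwork,
    shortest_paths,
)
from mircircuit.target_calling import PromoterBinding, TargetCall


def _call(m, g, cluster="c1", k=6, pos=0):
    return TargetCall(m, g, k, pos, "3UTR", cluster)


def _toy_network():
    calls = [
        _call("m1", "g1"), _call("m1", "g2"), _call("m2", "g2"),
    ]
    bindings = [PromoterBinding("g2", "m2", "p1", -500.0)]
    states = {"m1": "up", "m2": "down", "g1": "down", "g2": "ns"}
    return build_network(calls, bindings, states)


class TestBuildNetwork:
    def test_duplicate_calls_merge_into_one_edge(self):
        calls = [_call("m", "g", pos=p, k=k) for p, k in [(0, 6), (1, 7), (2, 8)]]
        net = build_network(calls)
        assert net.number_of_edges() == 1
        assert len(net.edges["m", "g"]["evidence"]) == 3

    def test_states_attached_missing_defaults_ns(self):
        net = _toy_network()
        assert net.nodes["m1"]["state"] == "up"
        assert net.nodes["g2"]["state"] == "ns"

    def test_edge_types_and_directions(self):
        net = _toy_network()
        assert net.edges["m1", "g1"]["edge_type"] == "miRNA_target"
        assert net.edges["g2", "m2"]["edge_type"] == "promoter_binding"

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            build_network([_call("x", "x")])

    def test_empty_inputs(self):
        net = build_network([], [])
        assert net.number_of_nodes() == 0


class TestInducedSubnetwork:
    def test_identity_when_all_kept(self):
        net = _toy_network()
        sub = induced_subnetwork(net, lambda n, a: True)
        assert set(sub.edges) == set(net.edges)

    def test_empty_when_none_kept(self):
        sub = induced_subnetwork(_toy_network(), lambda n, a: False)
        assert sub.number_of_nodes() == 0

    def test_idempotent(self):
        net = _toy_network()
        once = induced_subnetwork(net, activated_predicate)
        twice = induced_subnetwork(once, activated_predicate)
        assert nx.utils.graphs_equal(once, twice)

    def test_activated_predicate_keeps_up_mirna_down_protein(self):
        sub = induced_subnetwork(_toy_network(), activated_predicate)
        assert set(sub.edges) == {("m1", "g1")}

    def test_does_not_mutate_input(self):
        net = _toy_network()
        before = net.number_of_nodes()
        sub = induced_subnetwork(net, activated_predicate)
        sub.add_node("extra")
        assert net.number_of_nodes() == before


class TestFirstNeighbors:
    def _star(self):
        return build_network(
            [_call("m", g) for g in ("g1", "g2", "g3")],
            [PromoterBinding("g9", "m", "p", -10.0)],
        )

    def test_out_neighbors_of_star_center(self):
        assert first_neighbors(self._star(), {"m"}, "out") == {"g1", "g2", "g3"}

    def test_leaf_has_no_outgoing(self):
        assert first_neighbors(self._star(), {"g1"}, "out") == set()

    def test_both_equals_union_of_in_and_out(self):
        net = self._star()
        both = first_neighbors(net, {"m"}, "both")
        assert both == (
            first_neighbors(net, {"m"}, "in") | first_neighbors(net, {"m"}, "out")
        )

    def test_unknown_seed_rejected(self):
        with pytest.raises(KeyError, match="ghost"):
            first_neighbors(self._star(), {"ghost"}, "out")


class TestShortestPaths:
    def _chain(self):
        # m -> g1 -(binding)-> m2 -> g2
        return build_network(
            [_call("m", "g1"), _call("m2", "g2")],
            [PromoterBinding("g1", "m2", "p", -10.0)],
        )

    def test_direct_edge(self):
        result = shortest_paths(self._chain(), "m", "g1")
        assert result.length == 1 and result.direct
        assert result.paths == (("m", "g1"),)

    def test_three_step_alternating_path(self):
        result = shortest_paths(self._chain(), "m", "g2")
        assert result.length == 3
        assert result.paths == (("m", "g1", "m2", "g2"),)

    def test_disconnected_pair(self):
        result = shortest_paths(self._chain(), "g2", "m")
        assert math.isinf(result.length) and result.paths == ()

    def test_max_len_caps_reachability(self):
        result = shortest_paths(self._chain(), "m", "g2", max_len=2)
        assert math.isinf(result.length)


class TestDegreeRank:
    def _net(self, degrees, state="up"):
        net = nx.DiGraph()
        for g, d in degrees.items():
            net.add_node(g, kind="protein", state="ns")
            for i in range(d):
                m = f"m{g}_{i}"
                net.add_node(m, kind="mirna", state=state)
                net.add_edge(m, g, edge_type="miRNA_target", evidence=[])
        return net

    def test_dense_ranking_with_ties(self):
        ranks = degree_rank(self._net({"g1": 5, "g2": 3, "g3": 3, "g4": 1}))
        assert ranks.loc["g1", "rank"] == 1
        assert ranks.loc["g2", "rank"] == 2
        assert ranks.loc["g3", "rank"] == 2
        assert ranks.loc["g4", "rank"] == 3

    def test_state_filter_zeroes_degrees(self):
        ranks = degree_rank(self._net({"g1": 4}, state="down"),
                            restrict_to_state="up")
        assert ranks.loc["g1", "mirna_in_degree"] == 0

    def test_top_one_percent_of_200_unique_degrees(self):
        ranks = degree_rank(self._net({f"g{i:03d}": i for i in range(1, 201)}))
        assert int(ranks["top1pct"].sum()) == 2
        flagged = set(ranks[ranks["top1pct"]].index)
        assert flagged == {"g200", "g199"}

    def test_degree_total_equals_filter_passing_edges(self):
        net = _toy_network()
        ranks = degree_rank(net, restrict_to_state="up")
        n_up_edges = sum(
            1 for u, v, t in net.edges(data="edge_type")
            if t == "miRNA_target" and net.nodes[u]["state"] == "up"
        )
        assert int(ranks["mirna_in_degree"].sum()) == n_up_edges


class TestDecomposeModules:
    def _two_cliques(self):
        net = nx.DiGraph()
        a = ["a1", "a2", "a3", "a4", "a5"]
        b = ["b1", "b2", "b3", "b4", "b5"]
        for group in (a, b):
            for i, u in enumerate(group):
                for v in group[i + 1:]:
                    net.add_edge(u, v, edge_type="miRNA_target", evidence=[])
        net.add_edge("a1", "b1", edge_type="miRNA_target", evidence=[])
        return net, set(a), set(b)

    def test_two_cliques_joined_by_bridge(self):
        net, a, b = self._two_cliques()
        modules = decompose_modules(net, min_size=2)
        assert modules == [a, b] or modules == [b, a]

    def test_clique_split_is_the_max_modularity_bipartition(self):
        # exhaustive oracle: among all 2^9 bipartitions of the 10 nodes the
        # clique/clique split maximizes modularity, and greedy finds it
        net, a, b = self._two_cliques()
        undirected = nx.Graph(net.to_undirected())
        nodes = sorted(undirected.nodes)
        best, best_q = None, -math.inf
        for mask in range(1, 2 ** (len(nodes) - 1)):
            left = {n for i, n in enumerate(nodes) if mask >> i & 1}
            right = set(nodes) - left
            q = nx.community.modularity(undirected, [left, right])
            if q > best_q:
                best, best_q = {frozenset(left), frozenset(right)}, q
        assert best == {frozenset(a), frozenset(b)}
        greedy_q = nx.community.modularity(
            undirected, decompose_modules(net, min_size=2)
        )
        assert greedy_q == pytest.approx(best_q)

    def test_empty_network(self):
        assert decompose_modules(nx.DiGraph(), min_size=2) == []

    def test_min_size_filters_small_communities(self):
        net, a, b = self._two_cliques()
        assert decompose_modules(net, min_size=6) == []

    def test_modules_disjoint_and_within_input(self):
        net, a, b = self._two_cliques()
        modules = decompose_modules(net, min_size=2)
        seen = set()
        for module in modules:
            assert module <= set(net.nodes)
            assert not module & seen
            seen |= module

    def test_deterministic(self):
        net, _, _ = self._two_cliques()
        assert decompose_modules(net, 2) == decompose_modules(net, 2)


class TestZeroNoiseNetworkRecovery:
    def test_edge_set_matches_planted_truth(self, zero_noise_run):
        truth, result = zero_noise_run
        target = {
            (u, v) for u, v, t in result.network.edges(data="edge_type")
            if t == "miRNA_target"
        }
        binding = {
            (u, v) for u, v, t in result.network.edges(data="edge_type")
            if t == "promoter_binding"
        }
        assert target == truth.true_mirna_targets
        assert binding == truth.true_tf_mirna_edges

    def test_activated_subnetwork_matches_truth_filter(self, zero_noise_run):
        truth, result = zero_noise_run
        expected = {
            (m, g) for (m, g) in truth.true_mirna_targets
            if truth.true_states[m] == "up" and truth.true_states[g] == "down"
        }
        observed = {
            (u, v) for u, v, t in result.activated.edges(data="edge_type")
            if t == "miRNA_target"
        }
        assert observed == expected
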