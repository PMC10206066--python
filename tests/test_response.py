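import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_weighted_digraph
from pertnet.response import (
    EDGE_WEIGHT,
    NODE_WEIGHT,
    PathRecord,
    all_pairs_shortest_paths,
    assign_edge_weights,
    assign_node_weights,
    build_topnet,
    build_weighted_network,
    extract_topnet,
    rank_paths,
)


def _fc_table(log2fc: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"fc": [2.0**v for v in log2fc.values()], "log2fc": list(log2fc.values())},
        index=list(log2fc.keys()),
    )


def brute_force_min_cost(graph: nx.DiGraph, source: str, target: str):
    """Minimum path cost by exhaustive simple-path enumeration (oracle)."""
    best = None
    for path in nx.all_simple_paths(graph, source, target):
        cost = sum(graph.edges[u, v][EDGE_WEIGHT] for u, v in zip(path, path[1:]))
        if best is None or cost < best:
            best = cost
    return best


class TestWeights:
    def test_node_weight_is_floored_absolute_log2fc(self, line_network):
        fc = _fc_table({"A": -2.0, "B": 0.0, "C": 1.5})  # D unmeasured
        weighted = assign_node_weights(line_network, fc, epsilon=1e-6)
        nw = {n: weighted.nodes[n][NODE_WEIGHT] for n in weighted.nodes}
        assert nw == {"A": 2.0, "B": 1e-6, "C": 1.5, "D": 1e-6}

    @pytest.mark.parametrize(
        "nw_i, nw_j, expected",
        [(4.0, 1.0, 0.5), (1.0, 1.0, 1.0), (1e-6, 1e-6, 1e6)],
    )
    def test_edge_weight_formula(self, nw_i, nw_j, expected):
        g = nx.DiGraph([("i", "j")])
        g.nodes["i"][NODE_WEIGHT] = nw_i
        g.nodes["j"][NODE_WEIGHT] = nw_j
        assign_edge_weights(g)
        assert g.edges["i", "j"][EDGE_WEIGHT] == pytest.approx(expected)


class TestAllPairsShortestPaths:
    def test_line_graph_costs_and_lengths(self, line_network):
        weighted = build_weighted_network(line_network, _fc_table(
            {n: 1.0 for n in "ABCD"}))
        records = {(r.source, r.target): r for r in all_pairs_shortest_paths(weighted)}
        ad = records[("A", "D")]
        assert ad.path_cost == pytest.approx(3.0)
        assert ad.path_length == 3
        assert ad.normalized_cost == pytest.approx(1.0)
        assert ad.node_sequence == ("A", "B", "C", "D")
        # directionality: edges only point forward
        assert ("D", "A") not in records and ("B", "A") not in records

    def test_cheaper_two_hop_route_beats_direct_edge(self):
        g = nx.DiGraph()
        g.add_edge("A", "B", ew=0.7)
        g.add_edge("B", "C", ew=0.8)
        g.add_edge("A", "C", ew=2.0)
        records = {(r.source, r.target): r for r in all_pairs_shortest_paths(g)}
        ac = records[("A", "C")]
        assert ac.path_cost == pytest.approx(1.5)
        assert ac.node_sequence == ("A", "B", "C")

    def test_costs_match_brute_force_enumeration(self):
        """Dijkstra equals exhaustive simple-path minimum on 100 random graphs."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            g = random_weighted_digraph(rng, int(rng.integers(4, 9)))
            records = {(r.source, r.target): r for r in all_pairs_shortest_paths(g)}
            for s, t in itertools.permutations(g.nodes, 2):
                expected = brute_force_min_cost(g, s, t)
                if expected is None:
                    assert (s, t) not in records
                else:
                    assert records[(s, t)].path_cost == pytest.approx(expected)

    def test_costs_match_networkx_dijkstra(self):
        """Independent library cross-check on a larger random graph."""
        rng = np.random.default_rng(3)
        g = random_weighted_digraph(rng, 25)
        ours = {(r.source, r.target): r.path_cost for r in all_pairs_shortest_paths(g)}
        theirs = dict(nx.all_pairs_dijkstra_path_length(g, weight=EDGE_WEIGHT))
        for s, lengths in theirs.items():
            for t, cost in lengths.items():
                if s != t:
                    assert ours[(s, t)] == pytest.approx(cost)

    def test_stored_costs_consistent_with_sequences(self):
        rng = np.random.default_rng(5)
        g = random_weighted_digraph(rng, 10)
        for r in all_pairs_shortest_paths(g):
            recomputed = sum(
                g.edges[u, v][EDGE_WEIGHT]
                for u, v in zip(r.node_sequence, r.node_sequence[1:])
            )
            assert math.isclose(recomputed, r.path_cost, rel_tol=1e-9)
            assert r.path_length == len(r.node_sequence) - 1


def _record(source, target, cost, length):
    return PathRecord(source, target, (source, target), cost, length, cost / length)


class TestRanking:
    def test_ascending_normalized_cost(self):
        a = _record("X", "Y", 0.9, 1)
        b = _record("P", "Q", 0.8, 2)  # normalized 0.4
        assert rank_paths([a, b]) == [b, a]

    def test_ties_break_by_source_then_target(self):
        a = _record("B", "Z", 1.0, 2)
        b = _record("A", "Z", 1.0, 2)
        assert rank_paths([a, b])[0].source == "A"

    def test_single_path(self):
        a = _record("A", "B", 1.0, 1)
        assert rank_paths([a]) == [a]


class TestTopNet:
    @pytest.mark.parametrize("n_paths, fraction, k", [(25000, 0.0001, 3),
                                                      (10000, 0.0001, 1)])
    def test_ceiling_rule(self, n_paths, fraction, k):
        paths = [_record(f"s{i}", f"t{i}", 1.0 + i * 1e-6, 1) for i in range(n_paths)]
        top = extract_topnet(paths, fraction)
        assert len(top.selected_paths) == k

    def test_union_of_selected_paths(self):
        p1 = PathRecord("A", "C", ("A", "B", "C"), 1.0, 2, 0.5)
        p2 = PathRecord("B", "D", ("B", "C", "D"), 1.2, 2, 0.6)
        top = extract_topnet([p1, p2], 0.9999)
        assert top.nodes == {"A", "B", "C", "D"}
        assert top.edges == {("A", "B"), ("B", "C"), ("C", "D")}

    def test_empty_input_warns(self, caplog):
        with caplog.at_level("WARNING", logger="pertnet"):
            top = extract_topnet([], 0.5)
        assert top.nodes == set() and caplog.records

    def test_topnet_is_subgraph_and_rescoring_is_stable(self, small_study):
        _, network, _, datasets, _ = small_study
        from pertnet.diffexpr import fold_change_table

        fc = fold_change_table(datasets[0])
        top = build_topnet(network, fc, fraction=0.005)
        assert top.nodes <= set(network.nodes)
        assert top.edges <= set(network.edges)
        weighted = build_weighted_network(network, fc)
        for r in top.selected_paths:
            cost = sum(
                weighted.edges[u, v][EDGE_WEIGHT]
                for u, v in zip(r.node_sequence, r.node_sequence[1:])
            )
            assert math.isclose(cost, r.path_cost, rel_tol=1e-9)

    def test_perturbing_a_route_attracts_the_topnet(self):
        """Raising |log2FC| along one route strictly lowers its normalized
        cost and eventually makes it the top path."""
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("A", "D"), ("D", "C")])
        previous = math.inf
        for bump in [0.5, 1.0, 2.0, 4.0]:
            fc = _fc_table({"A": bump, "B": bump, "C": bump, "D": 0.1})
            weighted = build_weighted_network(g, fc)
            records = {
                (r.source, r.target): r for r in all_pairs_shortest_paths(weighted)
            }
            ac = records[("A", "C")]
            assert ac.normalized_cost < previous
            previous = ac.normalized_cost
        # at the largest bump the A->C path runs through B, and the TopNet
        # covering the three cheapest paths excludes the unperturbed detour D
        assert ac.node_sequence == ("A", "B", "C")
        top = build_topnet(g, fc, fraction=0.6)
        assert "D" not in top.nodes
        assert ("A", "B") in top.edges and ("B", "C") in top.edges
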