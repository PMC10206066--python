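"""Condition-specific weighted networks and shortest-path activity ranking.

The scaffold interaction network is contextualized to a condition by
overlaying node weights NW_i = |log2FC_i| (floored at a small epsilon so
edge weights stay finite) and edge weights

    EW_ij = 1 / sqrt(NW_i * NW_j),

which makes edges between strongly perturbed genes cheap.  All-pairs
shortest paths (Dijkstra from every source) are then ranked by activity,
defined as the path cost (sum of edge weights) normalized by the path
length (edge count): the lower the normalized cost, the higher the
activity.  The union of the top fraction of ranked paths is the top
perturbed network (TopNet).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from heapq import heappush, heappop

import networkx as nx
import pandas as pd

logger = logging.getLogger("pertnet")

NODE_WEIGHT = "nw"
EDGE_WEIGHT = "ew"


@dataclass(frozen=True)
class PathRecord:
    """One shortest path with its cost, length and normalized cost."""

    source: str
    target: str
    node_sequence: tuple[str, ...]
    path_cost: float
    path_length: int
    normalized_cost: float

    def sort_key(self) -> tuple:
        # ascending normalized cost = descending activity; deterministic ties
        return (self.normalized_cost, self.path_cost, self.source, self.target)


@dataclass
class TopNet:
    """Subnetwork induced by the top fraction of ranked paths."""

    graph: nx.DiGraph
    selected_paths: list[PathRecord]
    fraction: float
    total_paths: int

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)


def assign_node_weights(
    network: nx.DiGraph, fc_table: pd.DataFrame, epsilon: float = 1e-6
) -> nx.DiGraph:
    """Attach NW = max(|log2fc|, epsilon) to every node.

    Genes absent from the fold-change table get NW = epsilon: they stay
    traversable but maximally expensive.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    weighted = network.copy()
    log2fc = fc_table["log2fc"]
    for node in weighted.nodes:
        nw = abs(float(log2fc[node])) if node in log2fc.index else 0.0
        weighted.nodes[node][NODE_WEIGHT] = max(nw, epsilon)
    return weighted


def assign_edge_weights(weighted: nx.DiGraph) -> nx.DiGraph:
    """Attach EW = 1/sqrt(NW_i * NW_j) to every edge (in place)."""
    for src, tgt in weighted.edges:
        nw_i = weighted.nodes[src][NODE_WEIGHT]
        nw_j = weighted.nodes[tgt][NODE_WEIGHT]
        if nw_i <= 0 or nw_j <= 0:
            raise ValueError("node weights must be positive (floor first)")
        weighted.edges[src, tgt][EDGE_WEIGHT] = 1.0 / math.sqrt(nw_i * nw_j)
    return weighted


def build_weighted_network(
    network: nx.DiGraph, fc_table: pd.DataFrame, epsilon: float = 1e-6
) -> nx.DiGraph:
    """Node weighting followed by edge weighting, in one call."""
    return assign_edge_weights(assign_node_weights(network, fc_table, epsilon))


def _adjacency(weighted: nx.DiGraph) -> dict[str, list[tuple[str, float]]]:
    """Plain-dict adjacency with edge weights, neighbors in sorted order."""
    return {
        u: sorted((v, attrs[EDGE_WEIGHT]) for v, attrs in weighted.adj[u].items())
        for u in weighted.nodes
    }


def _dijkstra(
    adj: dict[str, list[tuple[str, float]]], source: str
) -> tuple[dict[str, float], dict[str, str], dict[str, int]]:
    """Single-source Dijkstra returning (dist, predecessor, hop count).

    Among equal-cost relaxations the lexicographically smallest
    predecessor wins, making reconstructed paths deterministic.
    """
    dist: dict[str, float] = {source: 0.0}
    pred: dict[str, str] = {}
    hops: dict[str, int] = {source: 0}
    done: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d, u = heappop(heap)
        if u in done:
            continue
        done.add(u)
        du_hops = hops[u]
        for v, weight in adj[u]:
            if v in done:
                continue
            nd = d + weight
            old = dist.get(v)
            if old is None or nd < old or (nd == old and u < pred.get(v, u)):
                dist[v] = nd
                pred[v] = u
                hops[v] = du_hops + 1
                heappush(heap, (nd, v))
    return dist, pred, hops


def _reconstruct(pred: dict[str, str], source: str, target: str) -> tuple[str, ...]:
    seq = [target]
    node = target
    while node != source:
        node = pred[node]
        seq.append(node)
    seq.reverse()
    return tuple(seq)


def all_pairs_shortest_paths(weighted: nx.DiGraph) -> list[PathRecord]:
    """One PathRecord per ordered reachable pair (s, t), s != t.

    Unreachable pairs are omitted.  Node sequences are reconstructed from
    the deterministic predecessor maps.
    """
    records: list[PathRecord] = []
    adj = _adjacency(weighted)
    for source in sorted(weighted.nodes):
        dist, pred, hops = _dijkstra(adj, source)
        for target in sorted(dist):
            if target == source:
                continue
            cost = dist[target]
            length = hops[target]
            records.append(
                PathRecord(
                    source=source,
                    target=target,
                    node_sequence=_reconstruct(pred, source, target),
                    path_cost=cost,
                    path_length=length,
                    normalized_cost=cost / length,
                )
            )
    return records


def rank_paths(paths: list[PathRecord]) -> list[PathRecord]:
    """Sort by ascending normalized cost (highest activity first).

    Ties break by (normalized_cost, path_cost, source, target) so the
    ranking is a deterministic total order.
    """
    return sorted(paths, key=PathRecord.sort_key)


def extract_topnet(ranked_paths: list[PathRecord], fraction: float) -> TopNet:
    """Union of nodes and edges of the top ``ceil(fraction * n)`` paths.

    The ceiling rule keeps the selection non-empty on any non-trivial
    input.  An empty path collection yields an empty TopNet with a
    warning.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    total = len(ranked_paths)
    graph = nx.DiGraph()
    if total == 0:
        logger.warning("no paths to select from; TopNet is empty")
        return TopNet(graph, [], fraction, 0)
    k = math.ceil(fraction * total)
    selected = ranked_paths[:k]
    for record in selected:
        seq = record.node_sequence
        graph.add_nodes_from(seq)
        graph.add_edges_from(zip(seq[:-1], seq[1:]))
    return TopNet(graph, selected, fraction, total)


def build_topnet(
    network: nx.DiGraph,
    fc_table: pd.DataFrame,
    fraction: float = 0.0001,
    epsilon: float = 1e-6,
) -> TopNet:
    """Full per-dataset stage: weight, run Dijkstra all-vs-all, rank, cut.

    Streams per-source results and reconstructs node sequences only for
    the selected top paths; the selection is identical to globally
    ranking full records (same (normalized_cost, cost, source, target)
    total order) but avoids materializing every path.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    weighted = build_weighted_network(network, fc_table, epsilon)
    adj = _adjacency(weighted)
    keys: list[tuple[float, float, str, str]] = []
    preds: dict[str, dict[str, str]] = {}
    for source in sorted(weighted.nodes):
        dist, pred, hops = _dijkstra(adj, source)
        preds[source] = pred
        keys.extend(
            (cost / hops[target], cost, source, target)
            for target, cost in dist.items()
            if target != source
        )
    keys.sort()
    total = len(keys)
    if total == 0:
        logger.warning("no paths to select from; TopNet is empty")
        return TopNet(nx.DiGraph(), [], fraction, 0)
    k = math.ceil(fraction * total)
    selected = [
        PathRecord(
            source=source,
            target=target,
            node_sequence=(seq := _reconstruct(preds[source], source, target)),
            path_cost=cost,
            path_length=len(seq) - 1,
            normalized_cost=norm,
        )
        for norm, cost, source, target in keys[:k]
    ]
    graph = nx.DiGraph()
    for record in selected:
        seq = record.node_sequence
        graph.add_nodes_from(seq)
        graph.add_edges_from(zip(seq[:-1], seq[1:]))
    topnet = TopNet(graph, selected, fraction, total)
    logger.info(
        "TopNet: %d/%d paths selected, %d nodes, %d edges",
        len(topnet.selected_paths), topnet.total_paths,
        topnet.graph.number_of_nodes(), topnet.graph.number_of_edges(),
    )
    return topnet


def paths_to_frame(paths: list[PathRecord]) -> pd.DataFrame:
    """Tabular view of path records (for the ranked-path TSV output)."""
    return pd.DataFrame(
        {
            "source": [p.source for p in paths],
            "target": [p.target for p in paths],
            "path_cost": [p.path_cost for p in paths],
            "path_length": [p.path_length for p in paths],
            "normalized_cost": [p.normalized_cost for p in paths],
            "node_sequence": ["|".join(p.node_sequence) for p in paths],
        }
    )
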