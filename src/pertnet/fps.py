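"""Cross-dataset meta-network and the Frequently Perturbed Subnetwork.

Per-dataset TopNets are merged into a combined (parent) network — node
and edge unions with a per-node count of how many datasets' TopNets
contain the node.  The Frequently Perturbed Subnetwork (FPS) keeps the
nodes present in at least ``min_count`` of the TopNets (4-of-5 in the
default configuration) together with the induced edges of the merged
network, capturing perturbations shared across tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger("pertnet")

DATASET_COUNT = "dataset_count"


@dataclass
class MergedNetwork:
    """Union of TopNets; each node carries its dataset frequency."""

    graph: nx.DiGraph
    n_datasets: int

    def counts(self) -> dict[str, int]:
        return {n: self.graph.nodes[n][DATASET_COUNT] for n in self.graph.nodes}


@dataclass
class FpsResult:
    """Nodes with dataset_count >= min_count and their induced edges."""

    graph: nx.DiGraph
    min_count: int

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)


def merge_topnets(topnets: list) -> MergedNetwork:
    """Node/edge union over TopNets, annotating per-node dataset counts.

    Accepts TopNet objects or bare DiGraphs (one per dataset).
    """
    if not topnets:
        raise ValueError("need at least one TopNet to merge")
    graphs = [t if isinstance(t, (nx.DiGraph, nx.Graph)) else t.graph for t in topnets]
    merged = nx.DiGraph()
    for g in graphs:
        merged.add_nodes_from(g.nodes)
        merged.add_edges_from(g.edges)
    for node in merged.nodes:
        merged.nodes[node][DATASET_COUNT] = sum(node in g for g in graphs)
    logger.info(
        "merged %d TopNets: %d nodes, %d edges",
        len(graphs), merged.number_of_nodes(), merged.number_of_edges(),
    )
    return MergedNetwork(merged, n_datasets=len(graphs))


def frequent_subnetwork(merged: MergedNetwork, min_count: int) -> FpsResult:
    """Induced subgraph on nodes with dataset_count >= min_count."""
    if not 1 <= min_count <= merged.n_datasets:
        raise ValueError(
            f"min_count must lie in [1, {merged.n_datasets}], got {min_count}"
        )
    keep = [
        n for n in merged.graph.nodes
        if merged.graph.nodes[n][DATASET_COUNT] >= min_count
    ]
    graph = merged.graph.subgraph(keep).copy()
    if not keep:
        logger.warning("FPS is empty at min_count=%d", min_count)
    else:
        n_components = nx.number_weakly_connected_components(graph)
        logger.info(
            "FPS (min_count=%d): %d nodes, %d edges, %d weakly connected components",
            min_count, graph.number_of_nodes(), graph.number_of_edges(), n_components,
        )
    return FpsResult(graph, min_count)
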