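"""Drug-target intersection with the FPS and co-drug candidate ranking.

Candidate co-drugs are ranked by the number of their known targets
captured by the frequently perturbed subnetwork; pairs of drugs can be
compared by their shared FPS targets, and a drug->target bipartite
network restricted to the FPS is emitted for visualization.  The
literature-based curation the shortlist then undergoes (excluding
already-tested combinations, preferring particular drug classes) is a
human step supported via an exclusion list, not an algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .fps import FpsResult
from .io import DrugTargetCatalog

logger = logging.getLogger("pertnet")


@dataclass
class DrugRanking:
    """Per-drug FPS target hits; rank 1 = most hits."""

    table: pd.DataFrame  # index: drug; columns: hit_count, rank, targets_in_fps

    def targets_in_fps(self, drug: str) -> set[str]:
        return set(self.table.loc[drug, "targets_in_fps"].split("|")) - {""}


def _fps_nodes(fps) -> set[str]:
    return fps.nodes if isinstance(fps, FpsResult) else set(fps)


def rank_drugs(
    catalog: DrugTargetCatalog, fps, exclude: set[str] | None = None
) -> DrugRanking:
    """Rank drugs by |targets ∩ FPS nodes|, descending.

    Ties break lexicographically by drug ID.  ``exclude`` drops drugs
    (e.g. combinations already in clinical use) before ranking.  An empty
    FPS yields an all-zero ranking with a warning.
    """
    nodes = _fps_nodes(fps)
    if not nodes:
        logger.warning("FPS is empty; all drug hit counts are 0")
    drugs = [d for d in catalog.drugs if not (exclude and d in exclude)]
    rows = []
    for drug in drugs:
        hits = sorted(catalog.targets[drug] & nodes)
        rows.append((drug, len(hits), "|".join(hits)))
    rows.sort(key=lambda r: (-r[1], r[0]))
    table = pd.DataFrame(
        rows, columns=["drug", "hit_count", "targets_in_fps"]
    ).set_index("drug")
    table["rank"] = range(1, len(rows) + 1)
    return DrugRanking(table[["hit_count", "rank", "targets_in_fps"]])


def shared_targets(
    catalog: DrugTargetCatalog, drug_a: str, drug_b: str, fps
) -> set[str]:
    """Intersection of the two drugs' FPS-restricted target sets."""
    for drug in (drug_a, drug_b):
        if drug not in catalog.targets:
            raise KeyError(f"unknown drug ID: {drug!r}")
    nodes = _fps_nodes(fps)
    return (catalog.targets[drug_a] & nodes) & (catalog.targets[drug_b] & nodes)


def build_bipartite(
    catalog: DrugTargetCatalog, drugs: list[str], fps
) -> nx.DiGraph:
    """Directed drug->target bipartite network restricted to the FPS.

    Nodes carry a ``kind`` attribute ("drug" or "target"); listed drugs
    appear even when they hit no FPS target.
    """
    if not drugs:
        raise ValueError("drug list must be non-empty")
    nodes = _fps_nodes(fps)
    graph = nx.DiGraph()
    for drug in drugs:
        if drug not in catalog.targets:
            raise KeyError(f"unknown drug ID: {drug!r}")
        graph.add_node(drug, kind="drug")
        for gene in sorted(catalog.targets[drug] & nodes):
            graph.add_node(gene, kind="target")
            graph.add_edge(drug, gene)
    logger.info(
        "bipartite network: %d nodes, %d edges",
        graph.number_of_nodes(), graph.number_of_edges(),
    )
    return graph
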