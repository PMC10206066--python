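"""Readers and writers for the pipeline's file formats.

Formats handled: TSV expression matrices (genes x samples, first column
gene IDs), two-/three-column edge lists and SIF interaction networks,
GMT gene-set collections, and two-column drug->target catalogs.  Every
reader has a matching writer and the pair is a round-trip identity on
valid inputs.

Gene identifiers are opaque strings matched exactly (case-sensitive);
probe-to-gene mapping is assumed to have happened upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger("pertnet")

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionDataset:
    """A genes x samples matrix of linear-scale normalized intensities.

    ``labels`` maps every sample (column) to ``"case"`` or ``"control"``.
    """

    matrix: pd.DataFrame
    labels: dict[str, str]
    name: str = "dataset"

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        missing = [s for s in self.matrix.columns if s not in self.labels]
        if missing:
            raise ValueError(f"samples missing from label map: {missing}")
        bad = {v for v in self.labels.values()} - {CASE, CONTROL}
        if bad:
            raise ValueError(f"labels must be 'case'/'control', got {sorted(bad)}")
        if not self.case_samples or not self.control_samples:
            raise ValueError("both case and control groups must be non-empty")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.matrix.columns if self.labels[s] == CASE]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.matrix.columns if self.labels[s] == CONTROL]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) loaded from a GMT file."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class DrugTargetCatalog:
    """Drug -> set of target gene IDs."""

    targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [d for d, t in self.targets.items() if not t]
        if empty:
            raise ValueError(f"drugs with empty target sets: {empty}")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.targets)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path: str | Path, labels: dict[str, str], name: str | None = None
) -> ExpressionDataset:
    """Read a TSV expression matrix (header = sample IDs, col 0 = gene IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionDataset(df, dict(labels), name=name or Path(path).stem)


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    dataset.matrix.to_csv(path, sep="\t", index_label="gene")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of (sample, case|control), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"])
    return dict(zip(df["sample"].astype(str), df["label"].astype(str)))


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


# ---------------------------------------------------------------------------
# interaction networks


def read_edge_list(path: str | Path, directed: bool = True) -> nx.DiGraph | nx.Graph:
    """Read a network from edge-list TSV or SIF.

    Two columns are read as (source, target); three columns are treated as
    SIF (source, relation, target).  Self-loops are removed and duplicate
    edges collapsed.
    """
    graph: nx.DiGraph | nx.Graph = nx.DiGraph() if directed else nx.Graph()
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: fewer than 2 columns")
            if len(fields) >= 3:  # SIF dialect: source relation target
                src, tgt = fields[0], fields[2]
            else:
                src, tgt = fields[0], fields[1]
            if src == tgt:
                n_self += 1
                continue
            if graph.has_edge(src, tgt):
                n_dup += 1
                continue
            graph.add_edge(src, tgt)
    logger.info(
        "read network %s: %d nodes, %d edges (%d self-loops, %d duplicates dropped)",
        path, graph.number_of_nodes(), graph.number_of_edges(), n_self, n_dup,
    )
    return graph


def write_edge_list(graph: nx.DiGraph | nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, tgt in sorted(graph.edges()):
            fh.write(f"{src}\t{tgt}\n")


def write_sif(graph: nx.DiGraph | nx.Graph, path: str | Path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for src, tgt in sorted(graph.edges()):
            fh.write(f"{src}\t{relation}\t{tgt}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then member genes, tab-separated."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT lines need >= 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                logger.warning("dropping empty gene set %r (line %d)", name, lineno)
                continue
            sets[name] = set(members)
            descriptions[name] = desc
    if not sets:
        logger.warning("GMT file %s contained no non-empty sets", path)
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# drug catalogs


def read_drug_catalog(path: str | Path) -> DrugTargetCatalog:
    """Read a two-column (drug, target-gene) TSV into drug->target sets."""
    targets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 2 columns (drug, target)")
            targets.setdefault(fields[0], set()).add(fields[1])
    if not targets:
        raise ValueError(f"drug catalog {path} is empty")
    return DrugTargetCatalog(targets)


def write_drug_catalog(catalog: DrugTargetCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug in sorted(catalog.targets):
            for gene in sorted(catalog.targets[drug]):
                fh.write(f"{drug}\t{gene}\n")
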