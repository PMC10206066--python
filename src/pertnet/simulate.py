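"""Synthetic benchmark generator with planted ground truth.

Emulates the pipeline's study design: several two-group expression
datasets (different "tissues") sharing one perturbed, connected module
of genes on a common scaffold interaction network, plus dataset-private
perturbed genes, plus a drug catalog in which one planted co-drug hits
the module harder than any decoy.  Because the truth is known, every
downstream stage — differential expression, TopNet extraction, the
frequency filter, drug ranking — can be scored for recovery.

Intensities are generated on the log2 scale (per-sample Gaussian noise
around a common baseline) and exponentiated, so the planted effect size
is directly an expected |log2 fold change|.  The sign of each planted
shift is drawn per gene per dataset: the pipeline consumes |log2FC| and
is direction-blind, so recovery must not depend on coherent direction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import derive_seed
from .io import CASE, CONTROL, DrugTargetCatalog, ExpressionDataset


@dataclass
class SimulationParams:
    """Knobs of the synthetic study.

    Defaults mirror the study conditions the benchmark emulates: five
    datasets, a planted |log2FC| of 2 (4-fold), per-sample log2 noise SD
    of 0.5 around a baseline intensity of 2^7, and a module carried by
    every dataset (share_fraction = 1).
    """

    n_nodes: int = 500
    n_edges: int = 2000
    n_datasets: int = 5
    samples_per_group: int = 10
    module_size: int = 15
    share_fraction: float = 1.0
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    baseline_log2: float = 7.0
    n_private_per_dataset: int = 10

    def __post_init__(self) -> None:
        if self.module_size >= self.n_nodes:
            raise ValueError("module_size must be < n_nodes")
        for name in ("n_nodes", "n_edges", "n_datasets", "samples_per_group",
                     "module_size", "effect_log2fc", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.share_fraction <= 1:
            raise ValueError("share_fraction must lie in (0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth of one simulated study."""

    module_nodes: set[str]
    per_dataset_extra: list[set[str]]
    codrug_id: str | None = None
    codrug_targets_in_module: set[str] = field(default_factory=set)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_network(params: SimulationParams, seed: int) -> nx.DiGraph:
    """Directed scaffold with a right-skewed (preferential-attachment) degree
    distribution, no self-loops, weakly connected, exactly ``n_edges`` edges.

    Construction: a growth phase attaches each new node to an existing
    node chosen with probability proportional to degree+1 (guaranteeing
    weak connectivity), then extra edges are added between degree-biased
    endpoint pairs; every edge gets a random orientation.
    """
    n, m = params.n_nodes, params.n_edges
    if m > n * (n - 1):
        raise ValueError(f"{m} edges infeasible for {n} nodes (directed simple graph)")
    if m < n - 1:
        raise ValueError(f"{m} edges cannot weakly connect {n} nodes")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n)
    graph = nx.DiGraph()
    graph.add_nodes_from(genes)
    degree = np.zeros(n, dtype=float)

    def add_oriented(i: int, j: int) -> bool:
        u, v = (i, j) if rng.random() < 0.5 else (j, i)
        for a, b in ((u, v), (v, u)):  # try the drawn orientation first
            if not graph.has_edge(genes[a], genes[b]):
                graph.add_edge(genes[a], genes[b])
                degree[a] += 1
                degree[b] += 1
                return True
        return False

    n_added = 0
    for i in range(1, n):  # growth phase: node i attaches among 0..i-1
        weights = degree[:i] + 1.0
        j = int(rng.choice(i, p=weights / weights.sum()))
        n_added += add_oriented(i, j)
    while n_added < m:
        weights = degree + 1.0
        i, j = rng.choice(n, size=2, replace=False, p=weights / weights.sum())
        n_added += add_oriented(int(i), int(j))
    return graph


def plant_module(
    network: nx.DiGraph, params: SimulationParams, seed: int
) -> PlantedTruth:
    """Choose a connected module by seeded breadth-first growth plus
    disjoint dataset-private perturbed gene sets."""
    if not nx.is_weakly_connected(network):
        raise ValueError("network must be weakly connected")
    rng = np.random.default_rng(seed)
    undirected = network.to_undirected(as_view=True)
    nodes = sorted(network.nodes)
    start = nodes[int(rng.integers(len(nodes)))]
    module: list[str] = [start]
    seen = {start}
    frontier = [start]
    while len(module) < params.module_size and frontier:
        nxt: list[str] = []
        for node in frontier:
            neighbors = [v for v in sorted(undirected.neighbors(node)) if v not in seen]
            rng.shuffle(neighbors)
            nxt.extend(neighbors)
            seen.update(neighbors)
        for v in nxt:
            if len(module) == params.module_size:
                break
            module.append(v)
        frontier = nxt
    if len(module) < params.module_size:
        raise ValueError(
            f"module_size {params.module_size} unreachable from seed node {start}"
        )
    module_set = set(module)
    pool = [g for g in nodes if g not in module_set]
    rng.shuffle(pool)
    need = params.n_datasets * params.n_private_per_dataset
    if need > len(pool):
        raise ValueError("not enough non-module genes for private perturbations")
    extras = [
        set(pool[d * params.n_private_per_dataset:(d + 1) * params.n_private_per_dataset])
        for d in range(params.n_datasets)
    ]
    return PlantedTruth(module_nodes=module_set, per_dataset_extra=extras)


def simulate_expression(
    network: nx.DiGraph,
    truth: PlantedTruth,
    params: SimulationParams,
    seed: int,
) -> list[ExpressionDataset]:
    """Two-group linear-scale intensity matrices, one per dataset.

    Control samples: log2 intensity ~ Normal(baseline_log2, noise_sd) per
    gene.  Case samples: the mean is shifted by +/- effect_log2fc (sign
    drawn per gene per dataset) for module genes — in the first
    ``round(share_fraction * n_datasets)`` datasets — and for that
    dataset's private genes; all other genes are unshifted.
    """
    if params.samples_per_group < 2:
        raise ValueError("samples_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    genes = sorted(network.nodes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_carrying = round(params.share_fraction * params.n_datasets)
    n_per = params.samples_per_group
    datasets = []
    for d in range(params.n_datasets):
        shifted = set(truth.per_dataset_extra[d])
        if d < n_carrying:
            shifted |= truth.module_nodes
        shift = np.zeros(len(genes))
        for g in shifted:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            shift[gene_idx[g]] = sign * params.effect_log2fc
        base = params.baseline_log2
        log_control = rng.normal(base, params.noise_sd, size=(len(genes), n_per))
        log_case = rng.normal(
            base + shift[:, None], params.noise_sd, size=(len(genes), n_per)
        )
        samples = [f"case_{i}" for i in range(n_per)] + [
            f"ctrl_{i}" for i in range(n_per)
        ]
        labels = {s: (CASE if s.startswith("case") else CONTROL) for s in samples}
        matrix = pd.DataFrame(
            np.exp2(np.hstack([log_case, log_control])), index=genes, columns=samples
        )
        datasets.append(ExpressionDataset(matrix, labels, name=f"dataset_{d}"))
    return datasets


def generate_drug_catalog(
    truth: PlantedTruth,
    network: nx.DiGraph,
    n_drugs: int = 11,
    codrug_hit_count: int = 5,
    decoy_hit_max: int = 2,
    seed: int = 0,
    off_module_targets: int = 4,
) -> DrugTargetCatalog:
    """Drug catalog with one planted co-drug.

    The co-drug gets exactly ``codrug_hit_count`` targets inside the
    planted module; every decoy gets a random 0..decoy_hit_max module
    targets; all drugs also receive off-module targets.  Records the
    co-drug's identity in ``truth``.
    """
    if codrug_hit_count > len(truth.module_nodes):
        raise ValueError("codrug_hit_count exceeds module size")
    if decoy_hit_max >= codrug_hit_count:
        raise ValueError("decoy_hit_max must be < codrug_hit_count")
    rng = np.random.default_rng(seed)
    module = sorted(truth.module_nodes)
    off_pool = sorted(set(network.nodes) - truth.module_nodes)
    width = len(str(n_drugs - 1))
    drug_ids = [f"drug{i:0{width}d}" for i in range(n_drugs)]
    codrug = drug_ids[int(rng.integers(n_drugs))]
    targets: dict[str, set[str]] = {}
    for drug in drug_ids:
        if drug == codrug:
            n_module = codrug_hit_count
        else:
            n_module = int(rng.integers(0, decoy_hit_max + 1))
        chosen = set(rng.choice(module, size=n_module, replace=False)) if n_module else set()
        n_off = off_module_targets + int(rng.integers(0, 3))
        chosen |= set(rng.choice(off_pool, size=min(n_off, len(off_pool)), replace=False))
        targets[drug] = {str(t) for t in chosen}
    truth.codrug_id = codrug
    truth.codrug_targets_in_module = targets[codrug] & truth.module_nodes
    return DrugTargetCatalog(targets)


def simulate_study(
    params: SimulationParams,
    seed: int,
    n_drugs: int = 11,
    codrug_hit_count: int = 5,
    decoy_hit_max: int = 2,
) -> tuple[nx.DiGraph, PlantedTruth, list[ExpressionDataset], DrugTargetCatalog]:
    """Generate one full study: network, truth, datasets, drug catalog.

    Each stage derives its own sub-seed from ``seed``.
    """
    network = generate_network(params, derive_seed(seed, "network"))
    truth = plant_module(network, params, derive_seed(seed, "module"))
    datasets = simulate_expression(
        network, truth, params, derive_seed(seed, "expression")
    )
    catalog = generate_drug_catalog(
        truth, network, n_drugs, codrug_hit_count, decoy_hit_max,
        derive_seed(seed, "drugs"),
    )
    return network, truth, datasets, catalog


def truth_manifest(truth: PlantedTruth, path: str | Path) -> None:
    """Write the planted ground truth as JSON for test harnesses."""
    payload = {
        "module_nodes": sorted(truth.module_nodes),
        "per_dataset_extra": [sorted(s) for s in truth.per_dataset_extra],
        "codrug_id": truth.codrug_id,
        "codrug_targets_in_module": sorted(truth.codrug_targets_in_module),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
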