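"""End-to-end convenience drivers over the stage modules.

`run_response_pipeline` takes real inputs (expression datasets plus a
scaffold network) through per-dataset TopNets, the merged meta-network
and the frequently perturbed subnetwork.  `run_synthetic_benchmark`
wraps that around the generator and scores recovery of the planted
truth: module recall/precision of the FPS and the rank of the planted
co-drug.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from . import diffexpr, drugs, fps as fps_mod, response
from .io import DrugTargetCatalog, ExpressionDataset
from .simulate import PlantedTruth, SimulationParams, simulate_study


@dataclass
class ResponseResult:
    topnets: list[response.TopNet]
    merged: fps_mod.MergedNetwork
    fps: fps_mod.FpsResult


@dataclass
class BenchmarkResult:
    truth: PlantedTruth
    result: ResponseResult
    ranking: drugs.DrugRanking
    recall: float
    precision: float
    codrug_rank: int


def run_response_pipeline(
    datasets: list[ExpressionDataset],
    network: nx.DiGraph,
    fraction: float = 0.0001,
    min_count: int = 4,
    epsilon: float = 1e-6,
) -> ResponseResult:
    """Per-dataset TopNets -> merged network -> FPS."""
    topnets = [
        response.build_topnet(
            network, diffexpr.fold_change_table(ds), fraction=fraction, epsilon=epsilon
        )
        for ds in datasets
    ]
    merged = fps_mod.merge_topnets(topnets)
    return ResponseResult(topnets, merged, fps_mod.frequent_subnetwork(merged, min_count))


def score_recovery(fps_nodes: set[str], module_nodes: set[str]) -> tuple[float, float]:
    """(recall, precision) of the FPS node set against the planted module."""
    if not module_nodes:
        raise ValueError("planted module is empty")
    hit = len(fps_nodes & module_nodes)
    recall = hit / len(module_nodes)
    precision = hit / len(fps_nodes) if fps_nodes else 0.0
    return recall, precision


def run_synthetic_benchmark(
    params: SimulationParams,
    seed: int,
    fraction: float = 0.001,
    min_count: int = 4,
    n_drugs: int = 11,
    codrug_hit_count: int = 5,
    decoy_hit_max: int = 2,
) -> BenchmarkResult:
    """Simulate one study, run the pipeline, score planted-truth recovery."""
    network, truth, datasets, catalog = simulate_study(
        params, seed, n_drugs=n_drugs,
        codrug_hit_count=codrug_hit_count, decoy_hit_max=decoy_hit_max,
    )
    result = run_response_pipeline(datasets, network, fraction, min_count)
    ranking = drugs.rank_drugs(catalog, result.fps)
    recall, precision = score_recovery(result.fps.nodes, truth.module_nodes)
    codrug_rank = int(ranking.table.loc[truth.codrug_id, "rank"])
    return BenchmarkResult(truth, result, ranking, recall, precision, codrug_rank)
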