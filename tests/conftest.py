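import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pertnet.io import CASE, CONTROL, ExpressionDataset
from pertnet.simulate import SimulationParams, simulate_study


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """3 genes x 4 samples with known group means (linear intensities)."""
    matrix = pd.DataFrame(
        {
            "c1": [200.0, 100.0, 50.0],
            "c2": [200.0, 100.0, 50.0],
            "k1": [100.0, 100.0, 100.0],
            "k2": [100.0, 100.0, 100.0],
        },
        index=["up", "flat", "down"],
    )
    labels = {"c1": CASE, "c2": CASE, "k1": CONTROL, "k2": CONTROL}
    return ExpressionDataset(matrix, labels, name="toy")


@pytest.fixture
def line_network() -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D")])
    return g


def random_weighted_digraph(rng: np.random.Generator, n_nodes: int) -> nx.DiGraph:
    """Small random directed graph with positive edge weights (for oracles)."""
    g = nx.DiGraph()
    nodes = [f"n{i}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < 0.35:
                g.add_edge(u, v, ew=float(rng.uniform(0.1, 3.0)))
    return g


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by read-only tests."""
    params = SimulationParams(
        n_nodes=80, n_edges=300, module_size=8, samples_per_group=5,
        n_private_per_dataset=4,
    )
    network, truth, datasets, catalog = simulate_study(params, seed=11)
    return params, network, truth, datasets, catalog
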