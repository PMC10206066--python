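import networkx as nx
import numpy as np
import pytest

from pertnet.diffexpr import differential_test, fold_change
from pertnet.simulate import (
    SimulationParams,
    generate_drug_catalog,
    generate_network,
    plant_module,
    simulate_expression,
    simulate_study,
)

SMALL = SimulationParams(
    n_nodes=100, n_edges=300, module_size=10, samples_per_group=5,
    n_private_per_dataset=4,
)


class TestGenerateNetwork:
    def test_size_and_connectivity(self):
        g = generate_network(SMALL, seed=1)
        assert g.number_of_nodes() == 100
        assert g.number_of_edges() == 300
        assert nx.is_weakly_connected(g)
        assert not any(u == v for u, v in g.edges)

    def test_deterministic_under_seed(self):
        a = generate_network(SMALL, seed=1)
        b = generate_network(SMALL, seed=1)
        assert list(a.edges) == list(b.edges)
        c = generate_network(SMALL, seed=2)
        assert set(a.edges) != set(c.edges)

    def test_degree_distribution_right_skewed(self):
        g = generate_network(SimulationParams(n_nodes=300, n_edges=1200,
                                              module_size=10), seed=0)
        degrees = np.array([d for _, d in g.degree()])
        assert degrees.max() > 4 * np.median(degrees)

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_network(SimulationParams(n_nodes=5, n_edges=30, module_size=2),
                             seed=0)


class TestPlantModule:
    def test_module_is_connected_with_requested_size(self):
        g = generate_network(SMALL, seed=3)
        truth = plant_module(g, SMALL, seed=4)
        assert len(truth.module_nodes) == 10
        sub = g.to_undirected().subgraph(truth.module_nodes)
        assert nx.is_connected(sub)

    def test_single_node_module(self):
        params = SimulationParams(n_nodes=100, n_edges=300, module_size=1,
                                  samples_per_group=5, n_private_per_dataset=4)
        g = generate_network(params, seed=3)
        truth = plant_module(g, params, seed=4)
        assert len(truth.module_nodes) == 1

    def test_private_sets_disjoint_from_module_and_each_other(self):
        g = generate_network(SMALL, seed=5)
        truth = plant_module(g, SMALL, seed=6)
        assert len(truth.per_dataset_extra) == SMALL.n_datasets
        all_private = set()
        for extra in truth.per_dataset_extra:
            assert len(extra) == SMALL.n_private_per_dataset
            assert not (extra & truth.module_nodes)
            assert not (extra & all_private)
            all_private |= extra

    def test_deterministic_under_seed(self):
        g = generate_network(SMALL, seed=3)
        assert plant_module(g, SMALL, seed=7).module_nodes == \
            plant_module(g, SMALL, seed=7).module_nodes


class TestSimulateExpression:
    def test_planted_effect_is_recovered_in_expectation(self):
        """Mean estimated |log2FC| over module genes within 0.2 of the
        planted 2.0, averaged over replicate simulations."""
        params = SimulationParams(
            n_nodes=60, n_edges=200, module_size=6, samples_per_group=10,
            n_datasets=2, n_private_per_dataset=3,
        )
        g = generate_network(params, seed=0)
        truth = plant_module(g, params, seed=1)
        estimates = []
        for seed in range(20):
            ds = simulate_expression(g, truth, params, seed=seed)[0]
            table = fold_change(ds)
            estimates.append(
                table.loc[sorted(truth.module_nodes), "log2fc"].abs().mean()
            )
        assert abs(np.mean(estimates) - params.effect_log2fc) < 0.2

    def test_non_module_gene_unshifted(self):
        params = SimulationParams(
            n_nodes=60, n_edges=200, module_size=6, samples_per_group=50,
            n_datasets=1, n_private_per_dataset=3,
        )
        g = generate_network(params, seed=0)
        truth = plant_module(g, params, seed=1)
        ds = simulate_expression(g, truth, params, seed=2)[0]
        quiet = sorted(
            set(g.nodes) - truth.module_nodes - set().union(*truth.per_dataset_extra)
        )
        mean_abs = fold_change(ds).loc[quiet, "log2fc"].abs().mean()
        assert mean_abs < 0.25  # pure noise at sd=0.5, n=50/group

    def test_share_fraction_limits_carrying_datasets(self):
        params = SimulationParams(
            n_nodes=60, n_edges=200, module_size=6, samples_per_group=20,
            share_fraction=0.6, n_private_per_dataset=3,
        )
        g = generate_network(params, seed=0)
        truth = plant_module(g, params, seed=1)
        datasets = simulate_expression(g, truth, params, seed=2)
        module = sorted(truth.module_nodes)
        shifted = [
            fold_change(ds).loc[module, "log2fc"].abs().mean() > 1.0
            for ds in datasets
        ]
        assert shifted == [True, True, True, False, False]

    def test_too_few_samples_rejected(self):
        g = generate_network(SMALL, seed=0)
        truth = plant_module(g, SMALL, seed=1)
        bad = SimulationParams(n_nodes=100, n_edges=300, module_size=10,
                               samples_per_group=1, n_private_per_dataset=4)
        with pytest.raises(ValueError, match=">= 2"):
            simulate_expression(g, truth, bad, seed=2)

    def test_null_gene_type_one_error_is_calibrated(self):
        """Welch rejections among unshifted genes at alpha=0.05 stay at the
        nominal rate (0.05 +/- 0.02) across >= 2000 genes."""
        params = SimulationParams(
            n_nodes=2200, n_edges=4400, module_size=10, samples_per_group=10,
            n_datasets=1, n_private_per_dataset=5,
        )
        g = generate_network(params, seed=9)
        truth = plant_module(g, params, seed=10)
        ds = simulate_expression(g, truth, params, seed=11)[0]
        quiet = sorted(
            set(g.nodes) - truth.module_nodes - set().union(*truth.per_dataset_extra)
        )
        assert len(quiet) >= 2000
        p = differential_test(ds).loc[quiet]
        rate = float((p < 0.05).mean())
        assert 0.03 <= rate <= 0.07


class TestDrugCatalog:
    def test_codrug_strictly_maximizes_module_hits(self):
        g = generate_network(SMALL, seed=0)
        truth = plant_module(g, SMALL, seed=1)
        catalog = generate_drug_catalog(
            truth, g, n_drugs=11, codrug_hit_count=5, decoy_hit_max=2, seed=2
        )
        assert len(catalog.targets) == 11
        hits = {d: len(t & truth.module_nodes) for d, t in catalog.targets.items()}
        assert hits[truth.codrug_id] == 5
        assert all(h <= 2 for d, h in hits.items() if d != truth.codrug_id)
        assert truth.codrug_targets_in_module <= truth.module_nodes

    def test_zero_decoy_hits_allowed(self):
        g = generate_network(SMALL, seed=0)
        truth = plant_module(g, SMALL, seed=1)
        catalog = generate_drug_catalog(
            truth, g, n_drugs=4, codrug_hit_count=3, decoy_hit_max=1, seed=5
        )
        # every drug still has off-module targets
        assert all(t - truth.module_nodes for t in catalog.targets.values())

    def test_unsatisfiable_constraints_rejected(self):
        g = generate_network(SMALL, seed=0)
        truth = plant_module(g, SMALL, seed=1)
        with pytest.raises(ValueError):
            generate_drug_catalog(truth, g, codrug_hit_count=99, seed=0)
        with pytest.raises(ValueError):
            generate_drug_catalog(truth, g, codrug_hit_count=3, decoy_hit_max=3,
                                  seed=0)

    def test_study_level_determinism(self):
        a = simulate_study(SMALL, seed=21)
        b = simulate_study(SMALL, seed=21)
        assert list(a[0].edges) == list(b[0].edges)
        assert a[1].module_nodes == b[1].module_nodes
        assert a[3].targets == b[3].targets
        assert a[2][0].matrix.equals(b[2][0].matrix)
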