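# Methods

## Overview

`pertnet` implements a network meta-analysis for nominating candidate
co-drugs from multi-tissue transcriptomics, together with the
summary-statistics machinery used to analyse the accompanying in-vivo
biochemistry panel. The pipeline has five computational stages:

1. **Differential expression.** For each two-group dataset, the fold
   change of gene *i* is the ratio of arithmetic group means of
   linear-scale normalized intensities, FC_i = SI_i(case)/SI_i(control).
   Significance comes from a two-sided Welch *t*-test on log2
   intensities. This is a declared stand-in for a moderated
   (empirical-Bayes) *t*: downstream computation consumes only
   |log2FC| as node weight and the DEG list, so variance moderation
   changes nothing structural, and the Welch test is exactly
   specifiable and calibrated (its type-I error on null genes is
   verified at 0.05 ± 0.02 in the test suite). A gene is a DEG when
   p < 0.05 and FC > 1.5 **or** FC < 1/1.5; the two-sided reading makes
   down-regulation symmetric with up-regulation, consistent with the
   direction-blind node weighting.
2. **Condition-specific weighted network.** The scaffold directed
   protein–protein interaction network is contextualized by node
   weights NW_i = max(|log2FC_i|, ε) and edge weights
   EW_ij = 1/√(NW_i·NW_j). Edges between strongly perturbed genes are
   cheap, so shortest paths gravitate toward perturbed regions.
3. **Path activity ranking (TopNet).** Dijkstra runs from every node
   (edge weights are positive, so Dijkstra applies); each ordered
   reachable pair contributes one shortest path with cost = Σ EW and
   activity = cost / path length (edge count). Paths are ranked by
   ascending normalized cost — lower normalized cost means higher
   activity — and the top fraction (default 0.01%) forms the TopNet:
   the union of the selected paths' nodes and edges.
4. **Frequently Perturbed Subnetwork (FPS).** Per-dataset TopNets are
   merged (node and edge unions, with a per-node count of contributing
   datasets), and nodes present in ≥ `min_count` TopNets (default 4 of
   5) are retained with their induced edges. The FPS captures
   perturbations shared across tissues and rejects dataset-private
   signal.
5. **Drug ranking.** Drugs are ranked by the number of their catalog
   targets captured by the FPS (descending; ties broken by drug ID).
   Shared targets of a drug pair and the FPS-restricted drug→target
   bipartite network support downstream inspection. Literature-driven
   curation of the shortlist is supported as an exclusion list applied
   before ranking, not as an algorithm.

Over-representation of any derived gene set against GMT collections
uses the one-sided (upper-tail) hypergeometric test, with the scaffold
network's gene set as the recommended universe for network-derived
queries; raw p < α gates the significance flag (a Benjamini–Hochberg
column is also emitted).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `deg_fc_threshold` | 1.5 | two-sided fold-change cutoff for DEGs (dimensionless ratio) |
| `deg_p_threshold` | 0.05 | raw p cutoff for the differential test |
| `top_path_fraction` | 1e-4 | fraction of ranked paths kept in the TopNet (0.01%) |
| `min_dataset_count` | 4 | TopNet frequency needed for FPS membership (of 5 datasets) |
| `node_weight_epsilon` | 1e-6 | floor on NW; keeps EW finite for unperturbed/unmeasured genes |
| `enrichment_alpha` | 0.05 | significance level for over-representation calls |

## Numerical and design choices

- **Epsilon flooring.** EW is undefined at NW = 0; flooring at ε keeps
  unperturbed genes traversable but maximally expensive. ε is
  configurable and logged with every run.
- **Ceiling selection.** The top-fraction cut keeps
  k = ⌈fraction · #paths⌉ paths, so the selection is never empty on a
  non-trivial input.
- **Deterministic ordering.** Path ranking uses the total order
  (normalized cost, cost, source, target); Dijkstra breaks equal-cost
  predecessor ties by the lexicographically smallest node ID. Repeated
  runs with the same inputs are byte-identical.
- **Streamed TopNet construction.** `build_topnet` keeps only
  (normalized cost, cost, source, target) keys plus per-source
  predecessor maps and reconstructs node sequences for the selected
  top-k paths only; a test verifies the selection is identical to
  globally ranking fully materialized records.
- **FPS edges by induction.** Frequency filtering applies to nodes
  (the stated criterion); edges enter the FPS as the induced edges of
  the merged network. Edge-frequency filtering would be stricter and is
  not what the node-frequency criterion describes.
- **Directionality.** The scaffold is treated as a directed network
  throughout; pair (s, t) and (t, s) are distinct paths.
- **Degenerate inputs.** Empty FPS and empty path sets are warned
  about, not fatal; genes with zero variance in both groups get p = 1
  (equal means) or p = 0 (unequal means, flagged by construction);
  nonpositive intensities are rejected because log fold change is
  undefined.

## In-vivo summary statistics

The biochemistry panel ships as a versioned table of per-group
(mean, SEM, n) for eight parameters across seven rat groups (normal and
diabetic controls, metformin 5 mg/kg, probucol 5 mg/kg, and three
metformin:probucol dose combinations; n = 3).

- **ANOVA from summaries.** With sd_i = √n_i·SEM_i, the within- and
  between-group sums of squares are algebraically identical to the
  raw-data one-way ANOVA; a property test verifies exact agreement with
  `scipy.stats.f_oneway` on random raw-data fixtures. Recomputed F
  statistics for glucose, triglycerides, total cholesterol, LDL, HbA1c,
  insulin and TBARS agree with the published values within 1% (the
  residual is rounding of the printed means/SEMs). The published HDL F
  statistic does not recompute from its own printed summaries
  (printed 39.36 vs recomputed 46.27); it is reported as found and
  excluded from reproduction checks rather than "fixed".
- **Dunnett's test.** Comparisons of k treatments against one control
  use the single-step equicorrelated multivariate-t critical value
  (correlation 1/2 at equal n; pairwise correlations
  √(n_i n_j/((n_i+n_0)(n_j+n_0))) otherwise). The joint probability is
  computed by conditioning on the shared control variate and the pooled
  SD, leaving a product of normal CDFs under a double Gauss quadrature
  (Hermite × Legendre); `brentq` inverts it between the Bonferroni
  brackets t_{α/2} and t_{α/2k}. A seeded 10⁶-draw Monte-Carlo sampler
  of the same multivariate t serves as an independent oracle (agreement
  within 0.02), and adjusted p-values are cross-checked against
  `scipy.stats.dunnett` on raw-data fixtures. The comparison family is
  the set of all non-control groups in the supplied panel (k = 6),
  which matches the published glucose CI [262.7, 335.2] at df = 14
  (implied critical value ≈ 2.911; ours 2.912).
- **Friedewald LDL** = TC − (HDL + TG/5) in mg/dl, warning above the
  formula's validity bound of TG = 400 mg/dl. Applied to printed group
  means this is approximate for treated groups if the original LDL was
  computed per animal before averaging.
- **Percent change** is 100·(reference − treated)/reference, positive
  for a reduction.

## Synthetic benchmark

The generator emulates the study design, not microarray physics:

- **Scaffold**: preferential-attachment growth plus degree-biased extra
  edges, randomly oriented — right-skewed degree distribution, weakly
  connected, exact edge count.
- **Planted module**: seeded breadth-first growth on the undirected
  view (default 15 genes), so the module is connected like a pathway
  neighborhood; per-dataset private perturbed sets (default 10 genes
  per dataset) are disjoint from the module and from each other. The
  private-set size is a generator choice: large enough that
  dataset-specific signal is present in every TopNet, small relative to
  the network so it cannot dominate.
- **Expression**: per-gene log2 intensities ~ Normal(7, 0.5) for
  controls; case means shift by ±2 (sign per gene per dataset) for
  module genes in carrying datasets and for private genes; 10 samples
  per group. `share_fraction` controls how many datasets carry the
  module, so the ≥4-of-5 filter can be exercised above (5/5) and below
  (3/5) threshold.
- **Drug catalog**: 11 drugs; the planted co-drug receives exactly 5
  module targets, decoys 0–2, all drugs get off-module targets.

Under the default benchmark conditions (500 nodes, 2000 edges, 5
datasets, path fraction 0.001, min_count 4), the FPS recovers the
planted module with mean recall ≥ 0.8 and precision ≥ 0.5 over 20
seeds, and the planted co-drug ranks first in ≥ 90% of seeds; with the
module in only 3 of 5 datasets, recall under the 4-of-5 filter
collapses (from ≈1.0 to ≈0.3 in our runs) — the frequency filter
behaves as designed. Recovery does not drop all the way to zero:
module genes that happen to be network hubs still enter non-carrying
TopNets as pass-through nodes on shortest paths between that dataset's
own perturbed genes, an effect inherent to path-union subnetworks (a
hub can be "frequently perturbed" by proximity rather than by its own
fold change). These problem
sizes were chosen so the whole benchmark (20 seeded pipeline runs)
completes in about a minute on one core while leaving the planted
signal at realistic strength rather than trivially separable.

What passing these tests does **not** show: robustness to probe-level
artifacts, batch effects, platform differences between tissues,
non-Gaussian intensity noise, or errors in the scaffold network — none
of which the generator models. The published full-scale counts
(6829-node/13,242-edge merged network, 225/471 FPS, 37 metformin FPS
targets, 41/45 bipartite) depend on a proprietary curated interaction
network and external database snapshots and are context, not
reproduction targets.

## Reproducibility

All randomness flows from a single seed; each stochastic stage derives
a deterministic sub-seed (CRC-mixed label, kept below 2³¹). Identical
parameters and seed give element-for-element identical networks,
matrices, catalogs and pipeline outputs, and the CLI writes a run
manifest (command, inputs, parameters, derived seeds) next to every
output.

## Known limitations

- Welch's t replaces moderated empirical-Bayes tests; with very few
  samples per group real studies would benefit from shrinkage.
- Gene identifiers are matched exactly; probe-to-gene mapping and
  cross-platform identifier harmonization are upstream concerns.
- The enrichment universe must be chosen by the user for real data;
  the packaged default (scaffold network genes) is only right for
  network-derived queries.
- `anova_from_summary` assumes the printed SEMs describe independent
  groups of the stated n; repeated-measures designs are out of scope.
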