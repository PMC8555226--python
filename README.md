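# targetfit

Network-centrality analysis of drug-target "fitness" on protein functional
networks.

Protein targets of selective approved drugs tend to occupy hub-like
positions in annotated protein interaction/association networks. Whether
that reflects biology or annotation bias is the question this package
operationalises: it computes node centrality, compares approved-drug
targets ("phase4" proteins) against exploratory targets within functional
classes, asks whether the scale-free shape of the network is what carries
the signal (via null models and degree-distribution projection), quantifies
literature-knowledge bias, and trains naive Bayes models that score
proteins by their network position.

It is aimed at computational biologists doing target prioritisation who
have an edge list (STRING `protein.links`, SIF or plain TSV) and per-protein
annotations, and at anyone who wants to study these statistical procedures
on fully synthetic networks with known planted structure.

## What it computes

**Centrality** (`targetfit.centrality`) — per node: degree k, average
shortest path, eccentricity, neighborhood connectivity, stress, betweenness,
closeness, local clustering coefficient, topological coefficient T, radiality,
and the degree-weighted composite log10(k·T). The topological coefficient of
node n is

    T(n) = mean over partners m of  J(n, m) / k(n),

where a partner shares ≥1 neighbor with n and J(n, m) counts shared
neighbors plus one if n–m is itself an edge; nodes with k ≤ 1 have T = 0
and are excluded from T-based statistics.

**Stratified comparison** (`targetfit.compare_stats`) — for each metric ×
target class, one-tailed t (pooled or Welch, F-test gated) and Mann–Whitney
(exact for small samples) tests of phase4 vs all-target values,
Benjamini–Hochberg corrected across the whole matrix.

**Degree-distribution fits** (`targetfit.degree_dist`) — a log-log
least-squares slope on a degree window, and a cumulative-space fit of
p_k ∝ (k + k_sat)^(−γ) · exp(−k/k_cut) with γ constrained to the
scale-free range [2, 3], plus a simulation-based fit-quality p-value.

**Null models and projection** (`targetfit.randomize`,
`targetfit.project`) — degree-preserving rewiring, Barabási–Albert,
Erdős–Rényi G(n, M) and Watts–Strogatz generators; projection of observed
node-set degree distributions onto the nulls (nearest-degree transfer for
scale-free targets, criteria-matched random sets with

    K_mean(r) ≈ K_min(r) + (K_max(r) − K_min(r)) · log K_mean(src) / log K_max(src)

for normal-degree targets).

**Bias diagnostics and models** (`targetfit.bias_scores`,
`targetfit.fitness_model`) — citation enrichment per class,
centrality–citation Spearman R², enrichment-vs-significance regressions,
hybrid disease-association scores, GO-term enrichment with a Cohen's-h
power gate, and mixed Gaussian/Bernoulli naive Bayes classifiers with
greedy feature selection, trained network-wide or per class.

**Synthetic studies** (`targetfit.synthetic_data`) — configuration-model
networks with tunable power-law exponent, planted hub-like phase4 sets
inside class-labeled groups, citation counts rank-correlated with degree
(Gaussian copula), disease counts correlated with citations, and GO-like
token assignments. Every generator is a pure function of config and seed.

## Worked example

```python
from targetfit import (SynthConfig, synth_study, compute_centrality_table,
                       stratified_comparison)

cfg = SynthConfig(n_nodes=1000, seed=7)     # planted hub factor 3 (default)
graph, ann = synth_study(cfg)
print(f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")

table = compute_centrality_table(graph)
matrix = stratified_comparison(
    table, ann,
    metrics=["degree", "average_shortest_path", "topological_coefficient"],
)
cells = matrix[(matrix.target_class == "all") & (matrix.test == "mann_whitney")]
for _, row in cells.iterrows():
    print(f"{row.metric:28s} adj_p={row.adjusted_p:.2e}  {row.direction}"
          f"  (n={row.n_phase4} vs {row.n_all})")
```

prints

```
network: 1000 nodes, 8010 edges
degree                       adj_p=1.07e-04  phase4_higher  (n=42 vs 60)
average_shortest_path        adj_p=1.07e-04  phase4_lower  (n=42 vs 60)
topological_coefficient      adj_p=3.15e-04  phase4_lower  (n=42 vs 60)
```

The planted approved-drug-like set (42 nodes, hub factor 3) is recovered:
its degree is significantly higher, and — as expected for hubs — its
average shortest path and topological coefficient are significantly lower
than the exploratory-target background, after multiple-testing correction.

The same analysis runs from the shell:

```bash
targetfit synth --n 1000 --seed 7 --out study/
targetfit centrality --in study/graph.tsv --out metrics.tsv
targetfit compare --metrics metrics.tsv --annotations study/annotations.tsv \
    --graph study/graph.tsv --out comparison.tsv
```

or end-to-end from a YAML config with `targetfit run-all --config cfg.yaml`,
which writes every stage output plus a manifest of seeds and content hashes.

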