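# Methods

This note documents the statistical conventions, numerical choices and
synthetic-data design behind `targetfit`, and what the test suite does and
does not establish.

## Centrality conventions

All metrics follow the NetworkAnalyzer-style definitions on simple
undirected graphs.

* Path metrics are computed inside each connected component; distances
  across components are never averaged. Average shortest path (asp) is the
  mean distance to the other nodes of the component; closeness is 1/asp;
  eccentricity the maximum distance. Singleton components are flagged
  undefined (NaN).
* Betweenness and stress count **unordered** source–target pairs with the
  node strictly interior. Betweenness is normalised by (n−1)(n−2)/2 per
  component, so it lies in [0, 1]. Both are accumulated in a single
  Brandes-style pass (stress uses the suffix-path count ψ with
  ζ_s(v) = σ_sv·ψ_s(v)); the ordered-pair totals are halved. Whether the
  original stress counted ordered or unordered pairs is not documented
  anywhere we could find; every downstream use is rank-based, and a global
  factor 2 does not change ranks.
* The topological coefficient T(n) averages J(n, m)/k(n) over all partners
  m sharing at least one neighbor with n, with J counting shared neighbors
  plus a +1 bonus when n–m is itself an edge. Nodes with degree ≤ 1 or
  without a sharing partner get T = 0 and are excluded from any statistic
  on T or on log10(k·T) — degree-1 nodes would otherwise dominate the
  T-vs-degree trend with structural zeros.
* Radiality is (Δ + 1 − asp)/Δ with Δ the component diameter: a strictly
  decreasing transform of asp, so every rank-based result involving it is
  equivalent to one on asp or closeness.
* The combined parameter is log10(k·T), base 10. Rank statistics and t
  statistics on it are invariant to the base (a log-base change is a
  positive scale factor).

## Two-sample machinery

* t tests are one-tailed. Variance pooling is gated by a two-sided F test
  at α = 0.05; Welch's form is used when the F test rejects **or** the
  sample-size ratio exceeds 3.
* Mann–Whitney is exact when min(n) ≤ 25 and the data are tie-free,
  otherwise the normal approximation with tie correction. The exact branch
  is validated against full enumeration of all label assignments for
  n1+n2 ≤ 10.
* Tests run one-tailed in the "approved-target more central" direction of a
  fixed orientation map: smaller is more central for average shortest path
  and topological coefficient, larger for everything else. The observed
  direction of the difference is reported for every cell regardless of
  significance.
* Benjamini–Hochberg correction is the standard step-up procedure applied
  jointly across metrics, classes and both test families; cells with fewer
  than two usable values in either group are flagged non-testable and do
  not count toward the correction factor m. The per-metric "average
  probability" row averages **raw** p-values over testable cells (the
  alternative, averaging adjusted values, is monotone-related and changes
  no conclusion; raw is the reproducible choice).

## Degree-distribution fits

* The simple fit is an ordinary least-squares slope of log10(count) vs
  log10(k) restricted to a degree window (default [100, 1000]) chosen to
  dodge low-degree saturation. It requires ≥ 5 distinct non-empty degrees.
  On sparse tails this estimator is biased (zero-count degrees are
  undefined in log space and get dropped), which is why the cumulative fit
  exists.
* The saturated fit models the pmf as (k + k_sat)^(−γ)·exp(−k/k_cut),
  normalised over the full integer degree grid of the data, cumulated
  numerically, and fitted by least squares on log10 P(K ≥ k) at the
  observed degrees. γ is constrained to [2, 3] by default (configurable;
  diagnostics can unconstrain it), k_cut is held infinite unless requested.
  Optimisation uses `scipy.optimize.least_squares` with bound constraints,
  five seeded starts and 1e−8 tolerances; k_sat is parameterised as
  log10(k_sat + 1) to keep the search well-scaled near zero.
* Fit quality: n_sim samples of the observed size are drawn from the
  fitted pmf; each sample's **absolute log-space cumulative residuals**
  against the model are pooled and compared with the observed residuals by
  a one-tailed Mann–Whitney test (observed larger ⇒ poor fit). The
  residual statistic fed to the comparison is a design choice; absolute
  log-cumulative residuals weigh every degree decade evenly, matching the
  fitting objective.

## Null models and projection

* Degree-preserving randomization is double-edge-swap rewiring with
  rejection of self-loops/duplicates; the target is `swaps_per_edge` × M
  accepted swaps and the achieved count is logged (small or rigid graphs
  admit fewer).
* The preferential-attachment null uses a complete seed graph on m0 nodes
  and m new edges per node: edge count exactly m0(m0−1)/2 + m(N−m0). At
  the published size (N = 17,161, m = m0 = 25) this gives 428,700 edges —
  within 0.3% of the count reported for the original tool, whose seed-graph
  convention is undocumented; we assert our construction's closed form.
* Watts–Strogatz keeps exactly N·K/2 edges for every rewiring probability.
  K = 48 (K must be even) realises a target mean degree of 49 at
  N = 17,161, i.e. 411,864 edges.
* Scale-free projection transfers each source degree to a node of equal
  degree in the target network, flooring below-minimum degrees at
  K_min(target) and mapping missing degrees to the nearest present value
  (ties toward the smaller degree); candidate nodes are drawn seeded,
  without replacement.
* Normal-degree projection selects random sets matching
  K_mean(r) = K_min(r) + (K_max(r)−K_min(r))·log10(mean K_src)/log10(K_max network)
  and s.d.(r) = (K_max(r)−K_min(r))·s.d.(log10 K_src), where K_src are the
  degrees of the **set** being projected and K_max the source network
  maximum. Logs are base 10; the mean rule's log ratio is base-invariant,
  the s.d. rule is not, and base 10 matches the log-scale plotting
  convention of the field. Sets are proposed from a normal distribution in
  degree space (clipped to the target's degree range) with the proposal
  moments adaptively rescaled toward the targets between tries; a set is
  accepted only when achieved mean and s.d. are both within a 5% relative
  tolerance (10,000 tries max, then an error reporting the best
  candidate). Shapiro–Wilk normality of each accepted set is reported, not
  enforced: clipping at the degree-range boundaries can legitimately
  depress it.

## Bias scores, hybrid scores, GO enrichment

* Percentiles are Hazen mid-rank percentiles, (rank − 0.5)/n with ties
  sharing mid-ranks — deterministic, inside (0, 1), and invariant under
  strictly monotone transforms. A fully tied column maps to 0.5.
* Relative citation abundance divides a class's phase4 citation fraction
  by its phase4 protein-count fraction. This is the natural candidate
  formula; published variants of this quantity are not arithmetically
  derivable from their printed tables, so we define and test only our own.
* The hybrid scores are unweighted arithmetic means of oriented
  percentiles: rns_like = mean(R, pct(k), 1−pct(asp)); r_top = mean(R,
  1−pct(T)); r_top_degree = mean(R, oriented pct(log10 k·T)). The
  combination rule is a package decision (the ingredients are standard,
  the formula is not); the orientation of the combined parameter defaults
  to higher-is-central and should follow the network-wide direction found
  by the stratified comparison.
* GO enrichment keeps the minimal prefix of count-ranked terms reaching
  95% of all associations, compares per-term protein frequencies between
  the phase4 and all-target groups, and gates on the power of a two-sided
  two-proportion test: Cohen's h = |2·asin√f1 − 2·asin√f2|, normal
  approximation, group n = protein counts. f1 = f2 gives power = α = 0.05
  by construction.

## Naive Bayes fitness models

* Mixed model: Gaussian class-conditionals for continuous features
  (variance floored at 1e−9, logged), Bernoulli with add-one smoothing for
  binary/token features, class priors from training frequencies, argmax
  posterior decision. Correlated centrality features compound their
  likelihood ratios — naive Bayes' "double counting" — which is exactly why
  it copes with the heavy phase4/background imbalance where other
  classifiers collapse to the majority class.
* Splits are stratified 70/30, preserving the label ratio. Greedy forward
  addition / backward elimination maximises the lexicographic objective
  (phase4 recall, then background F1, then accuracy) on an internal
  held-out split; ties prefer fewer features, then input order.
* Scope comparison experiments (per-class vs network-wide) run both scopes
  with the fixed full feature set: with five training positives per class,
  an internal selection split is noise-dominated and measurably degrades
  the per-class models, which would confound the scope contrast being
  measured.
* A known ceiling: a multiplicative hub boost b on a power-law background
  with exponent γ has a likelihood ratio that saturates at b^(γ−1)
  (≈ 5.2 for b = 3, γ = 2.5) for bulk degrees, so at class priors below
  ~1/(1+b^(γ−1)) no classifier can push bulk phase4 posteriors past 0.5
  from degree-family features alone. Distance-based features (asp,
  closeness, radiality) break the scale-invariance and lift per-class
  recall to ~0.75–0.85 at the default conditions; claims of near-perfect
  recall at small planted effects should be treated as over-fitting.

## Synthetic-data generator

The generator emulates the statistical structure of an annotated protein
functional network at desk scale; defaults are one-time choices:

* configuration-model degree sequence from a discrete truncated power law,
  exponent γ = 2.5 (inside the scale-free range [2, 3] that real protein
  networks fit), k_min = 3, k_max ≈ k_min·N^(1/(γ−1)); wiring by stub
  matching with bounded re-shuffle passes over conflicting stubs, an
  irreducible remainder dropped with a logged count;
* six target classes with proportions (0.10, 0.25, 0.10, 0.15, 0.05,
  0.35) and heterogeneous background hub character (class degree scales
  1.0, 2.0, 1.0, 4.0, 1.5, 2.5): real target classes occupy visibly
  different centrality ranges, and this heterogeneity is what makes class
  stratification (and per-class modelling) matter;
* 10% of each class as exploratory targets, 7 approved-drug targets per
  class (the size of the smallest real class set), each with its degree
  multiplied by the hub factor (default 3) before wiring;
* citation counts: Gaussian copula against degree ranks with Spearman
  ρ = 0.4 (giving centrality–citation R² ≈ 0.16, inside the 0.03–0.20 band
  observed on real networks), log-normal marginal (μ = 4.6, σ = 1.5 on the
  log scale — median ~100 citations, heavy tail); disease-association
  counts by the same construction against citations (ρ = 0.6, μ = 1.6,
  σ = 1.0);
* GO-like terms: vocabulary of 40 tokens with Zipf-skewed base rates
  (base probability 0.08), a 3× rate multiplier on each class's preferred
  vocabulary slice.

What the generator does **not** emulate: the true modular/hierarchical
community structure of signaling networks, curation-driven missingness
(edges absent because proteins are unstudied), literal database identifier
semantics, and any specific database's exact degree distribution. Passing
tests therefore show that the machinery recovers planted structure of the
assumed form at desk scale — not that any particular biological conclusion
holds on a real network.

## Problem sizes used by the test suite

Chosen as the package's own desk-scale study conditions: oracle
equivalence on 200 random graphs of ≤ 12 nodes (exact / 1e−9); type-I
calibration on 1000 null replicates of 800-node studies with 15 positives
per class (sizes where the t test's normal approximation is defensible;
the observed rejection rates of both families are compared with the 95%
binomial band for 1000 trials around α); exponent recovery on ten
20,000-node configuration networks; projection contrasts on ten 5,000-node
studies with k_min = 8 (the matched-set s.d. rule needs a degree span wide
enough to be feasible in the ER/WS nulls, as in the denser real network);
model-scope comparison on ten 1,500-node studies.

## Known limitations

* Path metrics are exact (no sampling) and pure Python: comfortable to a
  few thousand nodes; use `include_path_metrics=False` or the subset
  helpers beyond that.
* The exact Mann–Whitney branch requires tie-free data; integer-valued
  metrics at small n fall back to the tie-corrected approximation, which
  is slightly conservative there.
* The stub-matching configuration model can drop a few stubs on the
  heaviest nodes; degree sequences are exact only in distribution.
* One-tailed t tests on heavy-tailed metrics with very small groups
  (n ≈ 7) deviate from nominal size by up to ±0.02 in either direction
  depending on the metric's skew; the Mann–Whitney column is the robust
  reference in that regime, which is why both are always reported.
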