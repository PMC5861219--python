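# Methods

This note documents the models and procedures implemented in `woodnet`,
the reasoning behind parameter defaults and numerical choices, what the
synthetic-data generators do and do not emulate, and the package's known
limitations.

## Expression filtering and clustering

A gene counts as expressed when its VST-scale value exceeds
`vst_threshold` (default 3) in at least `min_samples` sections (default
2) of at least `min_trees` distinct trees (default 3 of 4).  "Samples"
are read as sections *within* a tree, so a gene must be reproducibly
detected in most trees rather than merely often in one.  The filter is
idempotent and order-preserving.  The VST itself is upstream of this
package: the filter consumes already-transformed values, and the
synthetic generator emits VST-scale values directly.

Scaling standardizes each gene row to mean 0, sd 1 across all sections
of all trees ("scaled per gene"); zero-variance rows map to all zeros
rather than NaN so that downstream code never sees non-finite values.
Unit-variance standardization (not min–max) is used because heatmap
interpretation is relative to each gene's own average expression.

Gene clustering uses correlation distance (1 − Pearson r) on the scaled
rows with average linkage; section clustering uses Euclidean distance
with Ward linkage.  The linkage method is exposed as a parameter since
the choice is conventional, not principled: average linkage is the
common default for correlation distances, Ward for Euclidean.  Cutting
the tree at k and k+1 yields nested partitions (agglomerative trees are
monotone for these linkages).

## Mutual information and CLR

Pairwise dependence is scored by plug-in mutual information (nats) on
the joint histogram after **equal-frequency** marginal binning with
`B = min(10, floor(√n))` bins.  Equal-frequency (quantile) binning is
robust to the skewed marginal distributions of expression data and makes
MI exactly invariant under strictly monotone transforms of either
profile.  Ties at bin boundaries are broken by stable rank order, so
binning is deterministic.  Zero-variance profiles return MI 0 by
convention.  Cell contributions are summed in sorted order so that
MI(x, y) and MI(y, x) are bit-identical.

The plug-in estimator is biased upward for independent data by roughly
(B−1)²/(2n); at the package's working point (n = 100 sections, B = 10)
the exact null expectation is ≈ 0.50 nats, noticeably above the
asymptotic formula because the joint histogram is sparse (one
observation per cell on average).  The CLR transform removes exactly
this kind of shared background: each MI value is z-scored against the
row distributions of both genes (means/sds computed excluding the
diagonal; negative z clipped at 0; rows with zero sd contribute 0) and
combined as `Z_ij = √(z_i(j)² + z_j(i)²)`.

The network keeps edges with `Z_ij ≥ 5`.  The threshold is interpreted
on the CLR z-composite scale — the score that defines the network links
here.  A structural consequence worth knowing: if a fraction *f* of a
gene's row is elevated, its row z-scores cannot exceed ≈ √((1−f)/f),
so at desk scale (300 genes, 20-gene modules) threshold-5 edges demand
strong, uniform within-module dependence.  This constraint shaped the
synthetic generator (below).

Edge signs come from the Pearson correlation of the two profiles
(exactly 0 resolves to "+"); genes with zero variance have no defined
sign and must be filtered upstream.

## Centrality, hubs and node categories

Betweenness is unweighted shortest-path betweenness with fractional
credit across equal-length paths, normalized by (N−1)(N−2)/2 so values
lie in [0, 1].  CLR weights are deliberately ignored for distances: no
weighted-path definition is adopted, and the hub analysis is about
topology.  Closeness uses the reachable-set form
`cl(v) = (r/(N−1)) · (r/S)` (r reachable others, S total distance),
which equals the reciprocal mean distance on connected graphs and
degrades gracefully on disconnected ones; isolated nodes score 0.

Ranking is descending (rank 1 = highest) with ties sharing the minimum
rank.  Hubs are genes with betweenness rank ≤ ceil(0.2 N); genes tied
with the cutoff value are all included rather than silently dropped.
When fewer than 20% of nodes have positive betweenness the tie rule
therefore floods the hub set with zero-betweenness genes — a degenerate
but faithful outcome of the stated rule on sparse graphs.

Node categories combine high/low (≥ 0.8-quantile) betweenness,
closeness and degree: center (H,H,H), connecting (H,H,L), monopole
(H,L,L), edge (low betweenness and degree, any closeness).  The four
patterns do not tile all eight combinations; remaining ones go to the
nearest pattern by Hamming distance with ties broken by the priority
center > connecting > monopole > edge (betweenness-first).  With all
metrics equal, everything is "high" by the ≥-quantile rule and every
node is a center.

Graph traversals are delegated to networkx (Brandes betweenness, BFS
distances); closeness is assembled by hand from BFS distances because
the formula above differs from networkx's normalization.  The test
suite checks both against an independent brute-force enumeration of
every shortest path on graphs of up to 12 nodes.

## Seed-gene modules

A module is the seed's first-order neighborhood at the threshold plus
all induced edges among members (an `order` parameter allows second
order).  The per-seed neighborhood view — not the connected component —
matches how individual transcription-factor modules are inspected.
Flags (hub, ethylene-responsive, TF family) are joins against the
centrality, response and annotation tables and never affect membership.

## Differential expression and the responsive-gene caller

The chain is: low-count filter → TMM normalization factors → log₂
counts per million → genewise cell-means OLS → empirical-Bayes variance
moderation → moderated t and BH q-values per genotype contrast.

* **Low-count filter.** The default removes a gene if *any* library has
  fewer than 10 reads.  This literal rule is stringent; the more common
  reading (keep genes with ≥ 10 reads in at least one library) is
  available as `mode="any_library_passes"`.
* **TMM.** The reference library is the one whose upper-quartile count
  fraction is closest to the mean; genewise M-values (30% trim) and
  A-values (5% trim) are doubly trimmed and combined with precision
  weights; factors are normalized to geometric mean 1.  The
  implementation agrees with edgeR's `calcNormFactors` to ~1e-10 in the
  test suite.
* **log-CPM.** `log2((count + 0.5) / (libsize·factor + 1) · 1e6)`; the
  prior count keeps zeros finite and the doubled prior in the
  denominator keeps the transform approximately scale-invariant.
  Precision (voom) weights are *not* implemented: the responsive-gene
  criterion operates on fold changes and q-values, which the
  moderated-t machinery provides without the extra fitting layer.
* **Genewise model.** OLS on the six genotype × treatment cell means;
  contrasts are ACC − mock within each genotype in log₂ units.  The
  replicate random effect of the original mixed-model description is
  simplified to a fixed-effects cell-means model: with exchangeable
  replicates the estimator stays closed-form and directly testable.  A
  duplicate-correlation extension is out of scope.
* **Moderation.** Method-of-moments fit of a scaled inverse-χ² prior on
  log s² (with di/trigamma corrections, trigamma inverted by Newton
  iteration); posterior `s̃² = (d0·s0² + d·s²)/(d0 + d)`; moderated t
  on d0 + d degrees of freedom.  When the observed spread of log s² is
  within chi-square sampling noise the prior df is capped at 1e9 and
  the prior variance is set to the geometric mean of s², so identical
  variances shrink to themselves.  Setting `prior_df=0` recovers the
  ordinary t exactly.  Against limma's `eBayes` the moderated t and p
  agree to ~1e-8 on heteroscedastic test data.
* **Caller.** Responsive ⇔ |log₂FC_WT| ≥ 1 AND q_WT < 0.01 AND
  |log₂FC_WT − log₂FC_g| ≥ 1 for **both** ethylene-insensitive
  genotypes.  "Two-fold" maps to 1 log₂ unit exactly; BH is applied
  within each genotype contrast separately.

The RT-qPCR utility `relative_expression` implements 2^−ΔCt.

## Enrichment

One-sided hypergeometric upper tail `P(X ≥ k)` per term, reported at
raw p < 0.05 — over-representation only, with no multiple-testing
correction by default, matching how enriched terms are conventionally
reported for these module-scale queries; a BH option exists.  The
universe defaults to the expressed-gene set, not the whole genome.
Query genes outside the universe are dropped with a warning.

## Synthetic data: what is emulated, and what is not

`generate_section_series` emulates the sectioned-stem design: 4 trees ×
25 sections, with zone widths P/C 5, Ex 4, SCW 9, CD 7 per tree (a
realistic imbalance chosen once; the per-zone counts are a modeling
choice, not a measured quantity).  Each planted module has a signal =
zone-peaked Gaussian bump (amplitude 4, width half the zone, repeated
per tree) **plus** a module-level per-section covariation
(sd 4, independent across modules and sections) shared by all members.
Members couple to the signal at 0.9 and add gene-specific variability
(3.5 × the baseline noise sd of 0.3); the designated hub carries the
signal at gain 2 with only baseline noise, making it the cleanest
reporter of the module and hence its most connected, most central node.
Anticorrelated members follow the negated signal shifted up by the
amplitude so they stay expressed.  Background genes are baseline noise.

Two design points deserve emphasis.  First, the module covariation is
deliberately *off* the positional axis: smooth position-driven profiles
would make every structured gene informative about every other through
the shared section coordinate, which inflates cross-module MI and, via
the CLR row statistics, suppresses genuine within-module z-scores.
Real co-expression includes exactly this kind of shared
section-to-section biological variation beyond the smooth developmental
gradient.  Second, the member-specific variability separates hub–member
MI from member–member MI (single vs double corruption of the shared
signal), which is what lets the hub's edges clear the threshold of 5 at
desk scale given the CLR cap discussed above.  Both scales vanish with
`noise_sd`, so the noiseless limit yields |r| = 1 for every
within-module pair.  The generator does **not** emulate: positionally
smooth expression autocorrelation between neighbouring sections,
tree-level batch effects, count-level noise (values are Gaussian around
the signal), or cross-module hub wiring — planted hubs earn their
betweenness as star centers of their own modules, not as bridges.
Passing recovery tests therefore show that the method finds
clean star-plus-clique structure at the stated noise levels, not that
it resolves arbitrarily entangled modules in real tissue.

`generate_count_experiment` emulates the 3 × 2 factorial: negative
binomial counts (gamma–Poisson, variance μ + φμ²; φ = 0.05), per-gene
abundances log-normal around 200 counts, library depth factors
log-normal with CV 0.2, 3 replicates per cell, and planted responders
whose mean is multiplied by 2^log₂FC in WT × ACC libraries only.  The
defaults (2,000 genes, 5% responders at |log₂FC| = 2) are the
operating conditions under which the caller's sensitivity and FDR are
measured.  No gene-specific dispersion trends, outlier libraries, or
batch structure are simulated.

`generate_annotation` plants terms that over-represent chosen modules
by an odds factor on a base rate (default 0.05); odds 1 is the null.
The TF-family table assigns families (NAC, MYB, ERF, EIN3, …) to a
random 8% of genes.

All generators draw every random quantity from a single
`numpy.random.Generator` seeded from the config, in a fixed order, so a
fixed config reproduces byte-identical outputs.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 20 (tests) or 10
(script) replicate section-series simulations at 300 genes × 100
sections; 10 replicate count experiments at 2,000 genes × 18 libraries
plus 10 matched null experiments; 5,000 genes for variance-prior
recovery; 200 random graphs of ≤ 12 nodes for the centrality oracles;
universes of ≤ 12 genes for exhaustive hypergeometric enumeration.
These sizes keep the full suite under a minute while leaving the
statistical assertions comfortable margins.

## Known limitations

* The CLR threshold of 5 is treated as a z-composite cutoff; other
  readings of the published cutoff scale (raw MI, another composite)
  would change edge sets.
* Closeness on disconnected graphs follows the reachable-set
  correction; literature conventions differ and absolute closeness
  values are not comparable across packages.
* The DE model omits voom precision weights and replicate random
  effects; with strongly unbalanced designs or correlated replicates
  the moderated t is only an approximation.
* Betweenness-based hub calling degenerates on very sparse graphs
  (boundary-tie flooding), which is visible on weakly structured
  synthetic data.
* Enrichment assumes a flat term structure (no ontology DAG
  propagation) and performs no cross-species homolog mapping.
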