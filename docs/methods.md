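# Methods

## Co-expression stability

The input is a genes × samples matrix of normalized expression
intensities. PCA is performed in sample space: each gene is a point
whose coordinates are its intensities across samples; columns (samples)
are mean-centered across genes before decomposition, and no
unit-variance scaling is applied by default (`scale_samples` enables
it). The retained dimension K is the smallest number of components
whose cumulative explained variance reaches `variance_threshold`
(default 0.8), clamped to at least 2 and at most the matrix rank.

The co-expression correlation of a gene pair, `cor_0`, is the
correlation of the two genes' score vectors over the K retained
components. We compute it **about the origin of PC space** rather than
re-centering each score vector by its own coordinate mean: per-component
scores are already centered over genes, and the uncentered form is
invariant to the arbitrary sign each SVD implementation assigns to a
component. On the full basis it equals the correlation of the
column-centered expression profiles. Correlations are clipped to
[−1, 1] after computation to absorb floating-point rounding.

`cor_i` (i = 1…N, default N = 10) is the same correlation computed with
the top i components removed. The stability is

    S = mean(cor_0, …, cor_N) / max(cor_0, …, cor_N)

so S = 1 exactly when all `cor_i` are equal and positive, and S is
small or negative when removing the leading components collapses the
correlation. The formula lives in one function
(`stability_from_correlations`) so an alternative combination rule is a
one-line change. Computing S requires K > N + 1; otherwise the code
raises with advice to lower N or raise the variance threshold. The
removal depth N = 10 reflects the approximate number of dominant
sample-wide effects (tissues, batches) in large compendia.

Pairs with `cor_0 < 0.2` are excluded (strict less-than; a pair at
exactly 0.2 is retained) and counted in a drop tally, separately from
pairs that are degenerate (zero variance in the retained subspace).
For retained pairs `cor_max ≥ 0.2 > 0`, so S ≤ 1 always holds, with
equality only for a constant positive trajectory.

## Network analysis

Profiles are joined onto a simple undirected PPI graph through a
protein→gene mapping (identity by default). Self-loops and duplicate
edges are dropped at load with logged counts; edges whose pair was
filtered remain in the graph but are flagged unprofiled and excluded
from all averages. Per protein, r̄ and S̄ are the arithmetic means of
`cor_0` and S over its profiled edges.

Hubs are proteins with ≥ 5 distinct profiled partners. For the
four-way classification, each profiled edge falls in exactly one window
of the (cor, stability) plane — category 1 strictly above both 0.5
cutoffs, categories 2–4 taking the complementary inclusive
inequalities, so an edge at exactly (0.5, 0.5) counts toward
category 3. A protein is a hub of every category with ≥ `min_partners`
(default 5) qualifying edges; since that permits multi-membership, a
dominant category (largest qualifying count, ties to the lower number)
is also emitted for single-label summaries.

Clustering coefficient (2T/deg(deg−1), zero below degree 2) and
betweenness centrality (pair-normalized by (n−1)(n−2)/2; disconnected
pairs contribute nothing) are computed with networkx on the full
profiled network, never on per-category subgraphs; the test suite
checks both against exhaustive brute-force oracles. Per-category means
carry standard errors computed as the sample (ddof = 1) standard
deviation over member hubs divided by √N; betweenness is additionally
displayed ×10⁴, the natural magnitude for networks of a few thousand
nodes.

Term enrichment per category uses the upper-tail hypergeometric
probability P(X ≥ k) through scipy's survival function (log-space,
stable). The population is the set of profiled-network proteins with at
least one annotation in the namespace under test — the conventional
background that keeps k/K consistent — and namespaces are tested
separately. Raw p-values are compared to α = 0.01 with no
multiple-testing correction by default (a Benjamini–Hochberg flag is
available). Term sets are flat; no ontology-graph propagation is
performed.

## Disorder, disease, landscapes

Disorder content is quantified from per-residue binary calls: only
maximal runs of ≥ 30 consecutive disordered calls count, and the
fraction divides the residues inside such runs by the full protein
length. Interactions are typed against a 30% threshold with the
boundary counting as disordered (both ≥ 30% → disordered pair, both
below → ordered pair, else mixed).

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when both groups have ≤ 12 observations and no ties, the
tie-corrected normal approximation (without continuity correction)
otherwise. Disease-class summaries report per-class mean ± SE of r̄ and
S̄, sorted by mean stability.

Landscapes are 2-D histograms over the (cor, stability) plane with
bin width 0.1 by default (configurable, e.g. 0.05); bins are half-open
[lo, hi) with the final bin closed, values are clipped into the axis
ranges, empty bins are masked and rendered gray. Overlay landscapes
average a per-item variable (e.g. disorder fraction) within each bin —
per-protein fractions are averaged, never pooled residues.

## Synthetic data

The generator produces the structure the analysis assumes, with ground
truth for every entity. Defaults define the standard study conditions;
all were fixed from the statistical design below before the end-to-end
tests were written.

* **Noise**: every gene starts as N(0, 0.3²) per sample.
* **Global background**: 10 global factors (per-sample N(0,1)) load on
  every gene with N(0, 0.087²) coefficients. They model pervasive
  batch/tissue structure and are essential: they occupy the top
  principal components (eigenvalues ≈ 3000 in scatter units) so that
  module factors (≈ 1600–1900) rank *below* the removal depth while the
  spike (≈ 5400+) ranks above it. Without them each module's shared
  factor would itself be a top PC and removing the top components would
  destroy robust correlations too — the generator would not reproduce
  the mechanism that makes the statistic work on real compendia.
* **Robust modules**: 10 modules of 8 genes share a per-module factor
  (N(0,1) per sample) with loadings ≈ N(1, 0.1). Within-module pair
  correlation ≈ 0.86, supported by every sample.
* **Fragile pairs**: 60 pairs share a signal that is zero except in 5
  spike samples (the same samples for all pairs, like a tissue batch;
  per-pair random sign) where it equals the spike amplitude 3.0 = 10×
  the noise sd. Sample-space correlation ≈ 0.58 that drops below 0.05
  when the spike samples are deleted.
* **Planted hubs**: 5 each of categories 1–3 and 2 of category 4 (the
  phenomenon is rare, but the code path must stay exercised), degree 16
  against a qualification threshold of 5. Category 1: strong shared
  factor, partners interconnected with probability 0.5 (intra-modular);
  category 2: partners load weakly (0.13) on the hub's factor, star
  topology (inter-modular); categories 3/4: spike-driven pairs at
  amplitude 1.7 / 3.0. The loadings were calibrated so edges land
  mid-window (cor₀ ≈ 0.9/0.35/0.4/0.7 for categories 1–4); degree 16
  absorbs the sampling noise of PC-space correlation estimates
  (sd ≈ 0.1 at K ≈ 60 retained components).
* **Network**: module cliques, hub stars (plus category-1
  partner–partner edges), fragile-pair edges, and sparse random
  background edges (rate 2×10⁻⁴) that mostly fail the cor₀ filter and
  exercise the unprofiled-edge path.
* **Annotations**: per category and namespace, a planted term covers
  90% of the category's planted hubs (for category 1, of the whole
  planted complex — its partners legitimately become category-1 hubs
  too, and a complex term annotates all subunits) plus a 2% background;
  broad root terms make most proteins annotated; decoy terms are
  unenriched. Residue strings realize a 0.35–0.6 disorder fraction via
  ≥ 30-runs for "high-disorder" proteins and only sub-30 runs (placed
  in disjoint chunks so they cannot merge) otherwise;
  `disorder_high_fraction` scales all group probabilities, so 0 means
  no long run anywhere. Disease/essential flags are drawn with
  pool-dependent probabilities (category-2 constructs elevated) so the
  disease and essential groups show lower correlation and higher
  stability as group means; disease classes map pools to
  "hematological" (robust, most stable), "metabolic" (weak-module) and
  "neurological" (fragile, least stable).

Everything is deterministic given the config seed (network and
annotation streams use fixed offsets of it).

### What the generator does not emulate

Real microarray noise (probe effects, normalization artifacts,
heavy-tailed intensities), scale-free degree distributions, correlated
annotation structure (ontology hierarchies), and mappings that are not
one-to-one. Passing tests therefore demonstrate that the
implementation is correct and that the statistic behaves as designed
under its own model assumptions — not that those assumptions hold for
any particular real compendium.

## Numerical and design choices

* PC-space correlations about the origin (sign-convention invariance;
  see above) and clipped to [−1, 1].
* K clamped to ≥ 2; stability refuses to run with K ≤ N + 1.
* Spearman rho uses mid-ranks for ties with the large-sample p
  approximation; constant vectors are an error, not NaN.
* Stability is NaN when `cor_max` is exactly 0 (never the case for
  retained pairs).
* Hub multi-membership is reported fully; dominant-category ties go to
  the lower category number.
* The disorder threshold boundary (≥ 30%) counts as disordered;
  the fraction's denominator is the full protein length.
* Pipeline problem sizes: the default synthetic conditions (2000 × 200,
  five seeds in the acceptance script) keep a full run at a few seconds
  while leaving dozens of pairs/hubs/terms per planted group, enough
  for stable medians and enrichment counts.

## Known limitations

The exact form in which the stability statistic combines the
correlation trajectory admits variants (e.g. rank-based versions);
only the mean/max form is implemented. Enrichment assumes flat term
sets. Betweenness on very large networks uses exact Brandes-style
computation through networkx with no approximation. File inputs must
fit in memory; the expression reader accepts a single matrix, not
chunked stores.
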