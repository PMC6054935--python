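# Methods

## Study design being modeled

The pipeline targets a common integrative design in autoimmune-disease
transcriptomics: a small two-group cohort (here ~10 cases vs ~10 matched
controls of PBMC samples) profiled on an array that measures protein-coding
genes, lncRNAs and miRNAs simultaneously, combined with three external
knowledge sources — a catalog of experimentally supported lncRNA targets
(genes and miRNAs), a catalog of miRNA gene targets, and a
protein–protein-interaction (PPI) database. The scientific question is
which modulated lncRNAs sit upstream of the densest, most interconnected
parts of the disease transcriptome, directly (lncRNA→gene) or through a
miRNA intermediate (lncRNA→miRNA→gene).

## Differential expression

Fold changes are computed on linear-scale group means and reported in the
signed-ratio convention (`r` when `r ≥ 1`, `−1/r` otherwise), so `|fc| ≥ 1`
always and down-regulation is negative. Significance is a one-way ANOVA on
log2 intensities; with two groups this is identical to the pooled-variance
two-sided t-test (asserted in the tests against an independently coded t
computation). Testing on the log scale and folding on the linear scale is
standard microarray practice and matches the convention of published
signed-FC tables.

Multiple testing uses the Bonferroni correction, `p_adj = min(1, m·p)`.
The decision p-value for the modulation call is configurable (`p_mode`):

* `bonferroni` (default) — the corrected value, matching the stated
  correction policy of the study design this pipeline reproduces;
* `raw` — the uncorrected ANOVA p, matching the scale of the p-values such
  studies actually print in their tables (at m in the tens of thousands, a
  printed p of ~0.005 cannot be a Bonferroni-corrected value).

The discrepancy between the two conventions is real and the pipeline
surfaces rather than resolves it. Note the power consequence: at n = 10/10,
a 2.5-fold effect and σ = 0.5 on log2, the raw mode detects planted effects
with sensitivity ≳ 0.99 at p ≤ 0.01, while the Bonferroni mode at the same
threshold has roughly 50% per-transcript power. The synthetic end-to-end
evaluations therefore run in raw mode; the package default remains
`bonferroni` for fidelity to the stated policy.

Degenerate inputs: two constant identical groups give p = 1 by convention;
duplicate transcript ids keep the record with the largest |fc| and warn.

## Target-selection cascade

Three stages, each a pure set/edge filter (all brute-force-checked in the
tests): (1) modulated lncRNAs with at least one annotated target;
(2) lncRNA→gene edges restricted to modulated genes and lncRNA→miRNA edges
restricted to an externally supplied modulated-miRNA list (this list is an
*input*, standing in for a prior miRNA study of the same cohort, not a
computation of this package — when absent, the pipeline substitutes its own
modulated-miRNA calls); lncRNAs retaining no edge are dropped;
(3) retained miRNAs expanded to their catalog gene targets, again
restricted to modulated genes. Identifiers are matched case-insensitively
after whitespace stripping; no alias resolution is attempted, because alias
mapping is database-specific. Both the post-annotation count and the
post-restriction count are reported, since either could be quoted as "the
selected lncRNAs".

## Tri-layer network and connectivity ranking

The gene scaffold is the PPI subgraph induced on the selected target genes;
isolated genes stay in the vertex set but are counted separately. Edge
enrichment replaces proprietary database statistics with a reproducible
null: draw uniform random gene sets of the same size from the catalog's
gene universe and count induced edges, `p = (1 + #{draws ≥ observed}) /
(n_perm + 1)` with `n_perm = 999` and a fixed seed; a Poisson approximation
(upper tail at the expected edge count under uniform vertex sampling) is
provided as a fast path and agrees with the permutation value on
Erdős–Rényi graphs within Monte-Carlo error (tested).

A lncRNA's connectivity score counts the distinct scaffold genes it reaches
directly or through *exactly one* miRNA hop. Deeper cascades
(lncRNA→miRNA→gene→…) are deliberately out of scope: one hop is what the
targeting annotations support without compounding false-positive edges.
Ranking is by descending score with lexicographic tie-break; the top-k
cutoff (default 7) is a presentation choice, not a statistical threshold.

## MCODE

MCODE is implemented from its published definition rather than wrapped,
since no maintained Python implementation exists.

* **Weighting.** For each vertex, take the closed neighborhood (vertex plus
  neighbors), find its highest k-core (k-core decomposition via the
  standard iterative minimum-degree removal), and score the vertex
  `k × density` of that core. Density is `2m/(n(n−1))`; a degree-0 vertex
  scores 0.
* **Growth.** Seeds are taken in decreasing weight order; growth admits
  unvisited neighbors with weight ≥ `(1 − cutoff) ×` seed weight,
  recursively; admitted vertices are globally marked, so complexes are
  vertex-disjoint.
* **Post-processing.** Haircut iteratively removes members with exactly one
  intra-complex edge; complexes with fewer than two members or without an
  internal k-core at the filter value are discarded; survivors are scored
  density × size and labeled M1, M2, … in non-increasing score order.

Defaults follow the published tool: node score cutoff 0.2, k-core filter 3
(interpreted, as in the tool, as a filter on detected complexes rather than
a pre-filter on the input graph), haircut on, fluff off. All tie-breaks
(seed order, growth order, labels) are lexicographic on vertex ids, making
results independent of edge insertion order.

A behavioral consequence worth knowing: because admission is relative to
the *seed's* weight, growth legitimately crosses bridges between regions of
similar weight (the two-triangle-plus-bridge example in the tests collapses
into a single 6-vertex complex of score 2.8). On planted-partition graphs
this means two planted modules merge whenever a stray inter-module edge
connects two high-weight vertices; detected complexes remain pure (they
never include sparse background vertices) and cover most planted vertices,
but one-to-one module recovery at high Jaccard is not guaranteed. The test
suite asserts the purity/coverage properties that do hold, and the
acceptance report includes the measured recovery fraction.

## Enrichment and targeting

Module enrichment is the upper-tail hypergeometric probability
`Σ_{j≥k} C(K,j)·C(N−K,n−j)/C(N,n)` computed via `scipy.stats.hypergeom.sf`
and verified against a direct-summation oracle to 1e-12. The background
universe defaults to measured genes that carry at least one annotation
(configurable to all measured genes) — annotation-free genes can never
contribute to an overlap, and including them deflates every p-value in the
same direction. Terms are flat GMT sets; no ontology-graph propagation.
Significance is raw p ≤ 0.05, with a Benjamini–Hochberg column always
emitted alongside.

The targeting matrix marks, per (lncRNA, module) cell, whether any retained
lncRNA→gene edge lands in the module (`direct`), any lncRNA→miRNA→gene
two-step path does (`indirect`), both, or neither; summaries report
per-lncRNA targeted-module counts and the fraction of modules targeted.

## Synthetic-data generator

The generator emulates the study conditions end to end with a recorded
ground truth:

* **Cohort.** Log-normal intensities: Gaussian on log2 around a
  per-transcript baseline ~ Uniform(4, 10), noise σ = 0.5 (the upstream
  probe-summarization algorithm of real arrays is proprietary and is not
  emulated; expression is generated directly on the summarized scale).
  Default 400 genes + 80 lncRNAs + 40 miRNAs, 10 cases vs 10 controls.
  Planted DE transcripts (25%/25%/30% per class) have their case mean
  shifted by ±log2(2.5), sign random per transcript and recorded.
* **Regulatory catalog.** Five planted regulator lncRNAs each target 3 DE
  miRNAs and 12 planted-module genes; each DE miRNA targets 8 genes biased
  3:1 toward planted-module genes; every other DE lncRNA receives
  Poisson(1) background edges to random targets. No self-edges or
  duplicates.
* **PPI.** A planted-partition graph over the gene universe: four disjoint
  12-gene modules inside the DE genes with within-module edge probability
  0.9 and background probability 0.02.
* **Annotations.** 20 GMT terms; one designated term per planted module
  draws ≥ 75% of its members from that module, the rest are uniform random
  gene sets of 8–25 genes.

Effect size (2.5-fold), noise (σ = 0.5 log2) and cohort size (10/10) are
the regimes of the design being modeled; the remaining defaults (fan-outs,
background rates, module sizes) were fixed once as representative of a
sparse curated catalog and are ordinary parameters, not estimates. What the
generator does *not* emulate: probe-level effects, batch effects, missing
values, correlated co-expression beyond the planted effects, hub-degree
(scale-free) PPI topology, and overlapping annotation hierarchies. Passing
tests therefore demonstrate the correctness of the algorithms under planted
truth, not calibration against real-array noise structure.

## Determinism and numerics

Every stochastic component takes an explicit seed: the generators draw from
independent seeded streams (so regenerating one artifact does not perturb
another), the permutation null is seeded, and all order-dependent
operations (filtering, ranking, complex labeling) carry deterministic
tie-breaks by id. Identical configuration + seed reproduces byte-identical
reports. p-values are never rendered as inequalities; full precision is
always written.

## Known limitations

* Two groups only; no covariates, paired designs or empirical-Bayes
  variance moderation.
* One miRNA hop; no deeper regulatory cascades and no edge confidence
  weights.
* MCODE complexes are disjoint (no fluff mode) and, as noted, can merge
  planted communities connected through high-weight bridges.
* The modulated-miRNA list is trusted as given; no re-testing of miRNA
  differential expression beyond the cohort's own calls.
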