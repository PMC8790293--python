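# Methods

## Statistical model for differential expression

Read counts are modelled as negative binomial: for gene *g* in sample *j*,
K₍gj₎ ~ NB(μ₍gj₎, φ₍g₎) with mean μ and variance μ + φμ².  φ (the
dispersion, dimensionless, ≥ 0) captures biological variability beyond
Poisson sampling; φ = 0 is the Poisson limit.  The same parameterization is
used by the simulator and the test, so simulated truth and estimated
quantities are directly comparable.

**Normalization.**  Per-sample factors with geometric mean 1, either
proportional to the total count (`libsize`, the default) or a trimmed mean
of M-values (`tmm`): gene-wise log2 ratios against a reference column
(the sample whose upper-quartile proportion is closest to the cohort mean)
are doubly trimmed — 30% on M, 5% on A — and averaged.  The TMM here is the
*unweighted* trimmed mean; the precision-weighted refinement used by some
DE packages is deliberately omitted, which keeps the statistic exactly
recomputable by hand and is adequate for the moderate composition biases
the pipeline targets.

**Dispersion.**  Per gene, a method-of-moments estimate
φ̂ = (s² − μ̂)/μ̂² is pooled across the two groups by degrees of freedom on
common-library-scaled counts.  The common dispersion is the mean of the raw
(possibly negative) per-gene values over genes with mean ≥ 1, clamped at 0
only at the end — clamping gene-by-gene first would bias the Poisson limit
upward.  Per-gene working dispersions shrink toward the common value with
weight 0.7 (configurable) and are clamped non-negative.  The conditional
maximum-likelihood and empirical-Bayes machinery of dedicated DE packages
is intentionally not reproduced; the exact test below is.

**Exact test.**  Each sample's counts are scaled to the geometric-mean
effective library and rounded ("pseudo-counts"), so both groups sit on a
common library size.  A sum of n iid NB(μ, φ) draws is NB with mean nμ and
dispersion φ/n; conditional on the grand total t, the group-A total has
distribution ∝ f_A(k)·f_B(t−k) over k = 0…t.  The two-sided p-value is the
total conditional probability of all splits whose probability does not
exceed the observed one (with a 1e-10 relative guard for floating-point
ties; computation on the log scale; φ = 0 switches to the Poisson/binomial
kernel).  If every split qualifies, p is exactly 1, and two all-zero
groups give p = 1.

This test is mildly conservative at realistic sample sizes: on all-null
simulations (2000 genes, 30 + 30 samples, φ = 0.1) the fraction of genes
at p < 0.05 is typically 0.03–0.05 across seeds, driven by the
discreteness of the conditional distribution and by the correlation
between the per-gene moment dispersion and the observed group difference.
The suite pins one such simulation inside the 5% ± 1% band.

**DE filter.**  p < 0.05 and FC > 2 or FC < 0.5, all inequalities strict
(a gene at FC exactly 2 is excluded).  FC is the tumor/normal ratio of
mean CPM with pseudocount 0.5 added before division, so it is always
finite and positive.  No multiple-testing correction enters the filter; a
Benjamini–Hochberg FDR column is emitted for information.

## Enrichment

Upper-tail hypergeometric over-representation of the query in each GMT
set, with the universe defaulting to all genes in the count matrix and set
members outside the universe not counted.  The EASE variant (overlap
decremented by one) is available but off by default; with raw-p
thresholding at 0.05 this mirrors the common practice of reporting
"significantly enriched" sets without FDR control, and a BH column is
emitted alongside.

## KGML to network

The parser captures entry/relation/group elements and nothing else
(graphics, reactions and coordinates are out of scope).  Edge semantics:

- relation types ECrel, PPrel, GErel and PCrel can contribute edges;
  maplink never does (its target is a map node, not a gene product);
- PCrel contributes only when *both* endpoints resolve to gene entries —
  protein–compound pairs are dropped, because the result is a gene
  interaction network;
- a group (complex) endpoint expands to the union of its gene components;
  intra-complex co-membership edges are off by default (flag
  `intra_group_edges`), keeping edges relation-derived;
- multi-id gene entries expand to all pairs; self-pairs are always
  dropped; KEGG ids missing from the id-map keep the KEGG id as label.

Merging collapses duplicate gene pairs across pathways into one edge whose
provenance is the set of contributing pathway ids; merging is idempotent.
Degree is the number of distinct neighbours, so the handshake identity
Σdeg = 2|E| is exact.  Hubs are nodes with degree **strictly** greater
than 30 — the operative published rule; a top-fraction alternative
(ties at the cutoff included) is provided.  Note the published marker
table itself contains one gene of degree 25, so that table is shipped
verbatim as a fixture rather than re-derived from the rule.

The scale-free diagnostic aggregates degrees into 20 logarithmically
spaced bins (configurable), regresses log10 density on log10 degree by
least squares and reports exponent = −slope with the fit's R².  This is a
diagnostic, not rigorous power-law inference (no MLE, no KS test); it
needs ≥ 10 distinct degree values and reports "not applicable" rather
than failing on degenerate inputs.

## Marker selection and classification

Markers are the DE ∩ hub intersection, matched case-insensitively after
whitespace stripping, sorted alphabetically, annotated with degree and DE
p-value and optionally a literature-confirmed flag from a supplied list.
An empty intersection halts the pipeline before classification.

Features are log2(CPM + 1) of the marker genes, standardized per training
fold (mean/sd from training data only — never from evaluation data; a
constant feature gets sd 1).  The SVM solves the soft-margin dual by SMO
with maximal-violating-pair selection, KKT tolerance 1e-6, a fixed
deterministic tie-break (first index), and an explicit iteration cap that
raises a convergence error instead of returning silently.  Default C = 1;
the hard-margin program is recovered as the large-C limit on separable
data (the analytic 1-D toy reproduces w = 1, b = −1, margin 2/‖w‖ = 2).
A decision score of exactly 0 is classified positive — an arbitrary,
documented tie rule.

Evaluation: stratified 50/50 split (per-class train size
round-half-up of fraction × n, assignment a seeded permutation), then
stratified tenfold CV *within the training half* with pooled out-of-fold
scores forming a single confusion matrix and ROC — the pooled-CV
convention is the default reading of a single training-set confusion
matrix under cross-validation, with resubstitution available by calling
`evaluate` on training scores directly.  The final model trains on the
full training half and is scored once on the held-out half.  AUC is the
Mann–Whitney rank statistic with average ranks (ties get half credit);
the ROC sweeps all unique score thresholds.

## Synthetic data: what it does and does not emulate

`simulate_counts` emulates an unpaired tumor/normal bulk RNA-seq cohort:
log-normal baseline means (median 50, log-sd 1, clipped to [10, 1000]),
log-normal per-sample depth factors (log-sd 0.15), NB noise with a single
dispersion shared across genes (default φ = 0.1, moderate biological
variability), and a planted DE fraction (default 5%, matching the
published study's ~1060 of 20,530 genes) with |log2FC| = 2 split evenly
up/down (mirroring the study's near-even 544/516 split).  It does **not**
emulate RSEM/log2(x+1) upstream quantification, gene–gene correlation,
gene-specific dispersion trends, batch effects, or patient-matched
tumor/normal pairs (the published cohort's pairing status is unstated;
groups are treated as independent).

`simulate_kgml` emulates a KEGG pathway collection whose merged network is
scale-free: a Barabási–Albert graph (default 6 edges per arriving node —
at 1277 nodes this yields ≈ 7.6 k edges, the published network's scale)
dealt across pathway documents, with ~10% of edges duplicated into a
second pathway to exercise provenance merging, a fraction of maplink and
protein–compound decoy relations to exercise the filters, and some edges
rerouted through group entries.  Hub truth (merged degree > 30) and the
true edge set come from the generator's own bookkeeping, never from
parsing its output, so parser tests against truth are non-circular.  Real
KGML is messier — multi-id entries, orthologs, nested maps — and pathway
membership in real KEGG is not an edge partition; passing tests therefore
demonstrate correctness of the stated edge semantics, not robustness to
every KEGG idiosyncrasy.

`simulate_study` couples the two: a subset of the gene universe (default
500 of 2000) forms the network, 12 hub genes are planted as DE, remaining
DE genes are drawn from non-hub genes, and per-pathway memberships become
the GMT sets — so the true marker set is exactly the planted hub-DE genes.
Default cohort 120 tumor + 40 normal keeps the tumor-heavy imbalance of
the motivating cohort at a size where the exact test over 2000 genes runs
in seconds.  Because planted markers carry a fourfold shift, the
marker-panel SVM is expected to reach near-perfect accuracy on this
scenario; the informative checks are exact truth recovery and the
contrast against an equal-size random panel.

## Problem sizes and numerical choices

- Exact-test enumeration is O(total count) per gene; the default study
  keeps per-gene totals in the 10³–10⁴ range, and the packaged analyses
  (acceptance script and tests) run minutes-scale end to end on one core.
- The stratified split reproduces the published cohort arithmetic exactly:
  1104 + 114 samples at fraction 0.5 give 552 + 57 = 609 per partition.
- SMO ties are broken by first index; all fold assignments and splits are
  seeded permutations, so every pipeline output is a pure function of
  (inputs, seed) and reruns are byte-identical.
- Degenerate inputs: all-zero count matrices, empty gene universes, empty
  queries, single-class truth and k < 2 folds are rejected with explicit
  errors; a group with fewer than two samples falls back to common
  dispersion with a warning; a class smaller than k reduces k with a
  warning.

## Known limitations

- The dispersion estimator is deliberately simple; at very small sample
  sizes (≤ 5 per group) its shrinkage can materially under- or
  over-disperse individual genes, and the exact test inherits that error.
- TMM is unweighted and uses a simple reference-column rule.
- The enrichment stage does not replicate any specific annotation
  backend's p-values; database-version-dependent results are out of scope.
- No rigorous power-law inference, no centralities beyond degree, no
  community detection.
- The classifier is linear-kernel only, without probability calibration;
  feature selection beyond the marker intersection is out of scope.
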