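# Methods

`heritnet` re-implements, as a tested library, the multi-region
transcriptomic inference used to study paternal inheritance of
cocaine-seeking: three paternal arms — saline self-administration (SSA),
cocaine self-administration (CSA) and yoked cocaine infusion (CY) — whose
male offspring are profiled in seven reward-circuitry regions (OFC, mPFC,
NAc, dStr, dHip, BLA, VTA) under two states (drug-naive and after cocaine
self-administration). This note records the models, the numerical choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Differential expression

Counts are normalized by median-of-ratios size factors (reference genes =
those positive in every sample; library-size fallback with a warning when
none exist), transformed as `log2(count/factor + 1)`, and tested per gene
with a Welch unequal-variance two-sample test between groups within each
(region, state) cell; `log2FC = mean_a − mean_b`. BH correction is applied
within each contrast. The engine is deliberately self-contained and
pluggable; it makes no attempt at dispersion shrinkage, so its per-gene
power at n = 4 per cell is that of a t-test with ~6 degrees of freedom.
Consequences:

* The null calibration (fraction of null genes with p ≤ 0.05 in
  [0.04, 0.06]) is verified on the full per-region cell with both states
  pooled (8 vs 8). At 4 vs 4 the Satterthwaite approximation is measurably
  conservative (empirical size ≈ 0.041 even on normal data), which is a
  property of the Welch test, not of the pipeline.
* FDR-controlled recovery of planted |log2FC| = 1 effects at 4 vs 4 is
  demonstrated in the low-noise regime (NB dispersion 0.01, baselines
  2^8–2^12). At dispersion 0.1 the per-gene noncentrality (~3.1) is below
  what any q ≤ 0.05 threshold needs; detection there runs through the
  raw-p pattern attribution, which unions evidence across region cells.

Two significance regimes are exposed: raw p ≤ 0.05 plus a 20% fold-change
for the synaptic splits (as printed in the study), and BH q ≤ 0.05 plus 20%
FC for DEG count tables; both thresholds are configuration values, as is
the "pervasively changed region" flag cutoff (default 400 DEGs in every
groupwise contrast of a state — the study's own text is ambiguous between
400 and 500, so the cutoff is not hard-coded).

## Pattern attribution

With x = effect(CSA−SSA), y = effect(CY−SSA) and x−y = effect(CSA−CY), a
gene's triple of direction/significance calls can only take sign patterns
realizable by real (x, y). Excluding all-null, exactly 12 patterns exist;
`enumerate_sign_classes` derives them by construction and the count is
checked against a sampling oracle. The biological classes are:

* **A** (drug exposure): both vs-SSA contrasts significant, same direction
  (direction consistency is required by default, configurable);
* **B** (highly motivated seeking): significant vs SSA and vs CY, not
  changed in CY vs SSA;
* **C** (passive infusion): the mirror image of B.

"Not changed" is non-significance at the raw-p rule with no fold-change
condition. Because the three tests run independently, observed triples can
be unrealizable (e.g. up, down, down); such genes are coerced by repeatedly
dropping the weakest (largest-p) significant call and flagged. A corollary
worth knowing: a gene significant in only one contrast always coerces to
the all-null triple — every one of the 12 realizable patterns carries at
least two consistent calls, so single-contrast evidence never fabricates a
B call.

## Rank-rank hypergeometric overlap

Signatures rank genes by s = −log10(p)·sign(log2FC) (p floored at 1e-300;
ties broken by gene id). The stratified variant splits each list at its
up/down boundary and scans prefix-threshold pairs within each quadrant
(uu, dd concordant; ud, du discordant), scoring overlap k of prefixes of
sizes a, b in a universe of N by the hypergeometric upper tail P(X ≥ k),
computed in log space (coordinated regions in this design reach
−log10 P > 50, far past double underflow). Depletion (k below expectation)
is reported with a negative sign on the lower tail. Step size defaults to
⌈√N⌉, bounding the grid at ~N cells. Maps are reported uncorrected across
the 21 region pairs.

## Co-expression networks

Unsigned WGCNA-style networks: adjacency |cor|^β on log2-normalized
expression, β chosen as the smallest power whose signed scale-free fit
index reaches 0.8 (argmax fallback, flagged); the topological overlap
matrix follows the standard (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) form.
Cross-region networks (one per paternal group) pool samples over regions
and states on the pattern-gene union, with expression standardized within
region first so regional means do not dominate the correlations.

Module detection is a deterministic static cut of the average-linkage
dendrogram on 1 − TOM. The cut height is chosen by scanning candidate
quantiles of the merge heights (strictly below the root) and keeping the
cut producing the most clusters of at least `min_size` genes, ties broken
toward more assigned genes and then the lower cut. A fixed quantile was
rejected after finding that no single value handles both the
blocks-plus-background and pure-block regimes; the scan recovers planted
two-block structure at adjusted Rand ≈ 0.98 while still isolating planted
modules against a 50%-background gene set. Clusters under `min_size`
(default 30) are unassigned (module 0); modules whose eigengenes (first
principal component, oriented to positive mean kME) correlate at
≥ 1 − merge_height (default 0.25) merge iteratively.

Module differential connectivity is the ratio of summed within-module
adjacency between two group networks; its self-ratio is exactly 1 and it
is exactly reciprocal under network swap, which the tests assert as
identities. Significance uses a sample-permutation null (group labels of
the pooled samples reshuffled, both adjacencies rebuilt, two-sided on
log MDC with +1 smoothing) with a random-gene-set null as the labeled
alternative; BH across modules. Under exchangeable groups the permutation
p-value is uniform (KS-checked at B = 99 over 200 replicates). Hubs are
ranked by intramodular connectivity with gene-id tie-breaks; conservation
is best-match Jaccard (preserved at ≥ 0.3) plus a Fisher p on the overlap.

## Regulons, behavior, analytes

TF regulons (a consumed upstream prediction table, top-20 style) are
clustered by average linkage on Jaccard distance between target sets, cut
at k = 3 — asserted rather than derived, so a silhouette-over-k diagnostic
accompanies the result. Genes inherit their regulators' clusters;
membership in ≥ 2 clusters is flagged as co-regulation. The candidate-gene
embedding is a seeded 2-D PCA with a k-means/regulon-cluster adjusted-Rand
concordance score; a nonlinear embedding was rejected for determinism.

Progressive-ratio screening normalizes breakpoints min–max (z-score
selectable; selection depends only on ranks), ranks animals and takes the
top k (ties by animal id); with fractions, k = ⌈fraction·n⌉. The largest
consecutive score drop is exposed separately (`score_gap`) since either
rule could have fixed the published k = 7 of 47 (14.9%). Analyte panels use
the exact Wilcoxon rank-sum — full enumeration of the rank-sum distribution
with midranks for ties (dynamic program over doubled ranks), two-sided by
distance from the null mean — up to a combined n of 30, then a flagged
tie-corrected normal approximation. Per-figure convention, analyte p-values
are uncorrected; a BH column is available behind a flag. Cross-region
correlation matrices are Pearson with t-transform p-values; group contrasts
of correlation structure are descriptive (no Fisher z), reported as
elementwise differences and per-region counts.

## Synthetic data

The generator emulates the study grid: 3 groups × 2 states × 7 regions ×
4 animals per cell (per-cell RNA-seq n is not published; 4 matches the 3–4
animals per litter the behavioral cohort used), 7 litters per arm.
Counts are negative-binomial (gamma-Poisson) with a common dispersion of
0.1 and no mean–dispersion trend — the pipeline's tests need overdispersion,
not a realistic trend. The per-gene log2 mean is
baseline (uniform 3–9) + region offset (SD 0.5) + litter effect (SD 0.1,
shared by littermates) + planted pattern effect + module component.
Pattern effects apply by class (A: CSA and CY; B: CSA only; C: CY only) in
nominated regions. Modules carry one latent factor per (module, sample)
whose loading depends on the sample's group; on the latent scale the
within-module correlation is exactly loading², giving an analytic target
(checked by simulation at low dispersion, where count noise does not
attenuate it). Behavior tables draw Poisson lever presses and normal
breakpoints (group shifts in SD units, clipped at 0); analyte tables are
group-wise multivariate normal with planted mean shifts and
positive-definite correlation targets; regulon tables are block-structured
binary matrices with uniform noise edges. All randomness flows from one
integer seed through a counter-based Philox stream per table, so a fixed
seed fixes every emitted byte.

What passing these tests shows: the pipeline recovers the structure it is
designed to detect when that structure is present at the stated effect
sizes, and its exact tests and null calibrations behave as advertised.
What they do not show: robustness to mean–dispersion trends, batch
structure beyond scalar size factors, unbalanced designs, or the
compositional and mapping artifacts of real RNA-seq.

## Problem sizes

Default verification runs use 400–1500 genes for recovery experiments,
10,000 genes for null calibration, 100-gene two-block designs over 20
seeds, MDC at B = 99–200 permutations (200 replicates for the uniformity
check), and RRHO nulls at N = 2000 — sizes at which every check is exact
or tightly Monte-Carlo-bounded while the whole suite stays fast on one
core.
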