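# Methods

## Scope and model

The package analyses Illumina-style methylation-array data represented as
beta values (methylation fractions in [0, 1], probes × samples) with a
probe manifest carrying genomic coordinates and annotation categories.  The
statistical chain assumes two-group comparisons of cell-line-like samples
(no covariates, no paired designs) and treats probes as conditionally
independent given their genomic position; spatial structure enters only
through DMR chaining.

## Moderated t and its prior

Testing happens on M-values, `M = log2(β/(1−β))`, where array noise is
approximately homoscedastic.  For probe *i* with pooled residual variance
`s²ᵢ` on `d = nₐ + n_b − 2` df, the prior `(d₀, s₀²)` is estimated by the
classical moment-matching on `log s²`: `e = log s² − ψ(d/2) + log(d/2)` has
mean `log s₀²`-related and excess variance `ψ′(d₀/2)`; `d₀` comes from a
Newton inversion of the trigamma function.  When the empirical excess
variance is non-positive the prior degenerates to `d₀ = ∞` (fully shared
variance); when only one probe has positive variance the same fallback
applies.  Posterior variances are the usual convex combination and the
two-sided p comes from a t distribution on `d₀ + d` df (normal when
infinite).  `d₀` may be forced by the caller — `d₀ = 0` reproduces the
ordinary pooled t exactly, which the tests assert against a textbook
example, and `d₀ = ∞` reproduces the fixed-variance limit.

Benjamini–Hochberg q-values are reported alongside, but the DMP calls
themselves gate on raw p (≤ 0.01) and effect size (|ΔM| ≥ 2), the
convention this analysis family uses.  "ΔM" is the difference of group
means on the M-value scale (the linear-model coefficient often printed as
log2FC); the beta-scale difference Δβ is carried through for
interpretation.

## DMR aggregation

Probes significant at the probe-level gate are sorted per chromosome and
chained while consecutive gaps are ≤ 1000 bp; chains need ≥ 3 CpGs.  Member
evidence combines as a signed Stouffer statistic (`zᵢ =
sign(ΔMᵢ)·Φ⁻¹(1−pᵢ/2)`, p floored at 1e-300, `Z = Σzᵢ/√k`), a deliberate,
oracle-testable replacement for kernel-smoothed region statistics.  It
shares their qualitative behaviour (coherent neighbours reinforce, opposed
neighbours cancel) but not their exact values, so region counts from other
implementations are not expected to be reproduced bit-for-bit.  The region
effect `mean_delta_beta` is the mean over member CpGs of the group-mean
beta difference; `tss_within_2000bp` is true when any member is annotated
TSS1500/TSS200.

## Enrichment and uncertainty

Region-set enrichment is computed at probe level: a probe belongs to a BED
set when its 0-based coordinate falls in any half-open interval.  The 2×2
table partitions the universe (all filtered array probes) into
query/background × in/out; p is the standard two-sided Fisher exact test;
the effect size is the sample odds ratio with Haldane–Anscombe +0.5 applied
to all cells when any cell is zero, and a Woolf log-scale 95% CI.  The
conditional-MLE odds ratio used by some R implementations differs slightly;
the cross-product form was chosen for its closed form and exact testability.

Annotation proportions over the island-relation and gene-feature families
carry 95% percentile-bootstrap CIs from resampling the probe set with
replacement (default 1000 iterations, seeded).  Nested-simulation coverage
of these intervals is measured by the acceptance suite (93–97% observed at
n = 500).

## Similarity

Distances are plain euclidean over all probes.  Clustering is Ward in the
"D2" sense — Lance–Williams on squared distances, heights reported on the
distance scale — delegated to `scipy.cluster.hierarchy.linkage(method="ward")`,
which implements exactly that recurrence; one test cross-checks the merge
heights against R's `hclust(method = "ward.D2")` on the same distance
matrix.  scipy's deterministic merge-order tie-break is used as-is.  Beta
density profiles use a Gaussian KDE (Silverman bandwidth) with boundary
reflection at 0 and 1, renormalised to integrate to one on [0, 1].

## Lineage/program scores

The scoring PCA centres and unit-scales each probe (dropping zero-variance
probes) and fixes each component's sign by making its largest-|loading|
entry positive.  Scores are built from a loading vector in three steps:

1. **Ranking** — loadings sorted ascending, ties broken by probe id.
2. **Tail selection (knee)** — each tail (negative and positive loadings)
   is ordered by |loading| descending and cut at a knee of the
   |loading|-vs-rank curve.  A single maximum-chord-distance knee is
   unreliable here: with tens of informative CpGs against thousands of
   background CpGs the chord is dominated by the long flat stretch and the
   global knee lands inside the background.  The implementation therefore
   iterates: re-apply the knee to the retained head while the knee point
   lies below the chord (the segment is convex there, i.e. still contains
   the informative/background drop); when the knee point flips above the
   chord the head is a shallow plateau and that cut is the boundary.  A
   segment whose best chord deviation is within the order-statistic wiggle
   of a homogeneous sample (`max(0.1, 1.5/√n)` in axis-normalised units) is
   kept whole.  The procedure is deterministic and reduces to the plain
   knee on short curves.  `top_k` and `abs_threshold` selection are
   available as alternatives.
3. **Scoring** — raw score per sample `= sign · Σ loadingᵢ·βᵢ` over the
   selected CpGs; Z-normalisation parameters (mean, sample SD) are fitted
   on the reference cohort and frozen in the model, so projections are
   leakage-free.  A `renormalize_all` pipeline option instead standardises
   over reference and projected samples jointly, since either convention is
   defensible.  Projection tolerates up to 10% missing selected probes,
   imputing the reference mean beta with a warning.

Component choice is user-driven; `component_group_separation` reports a
one-way ANOVA F per component as an aid.  When the user can label the axis
of interest (as with reference entities of known phenotype),
`axis_loadings` refines the choice: it returns the direction within the
span of the top components (default six) maximising the Fisher discriminant
of sample scores between the two sides of the axis.  This matters because
two planted axes of similar strength give near-degenerate eigenvalues, and
plain eigenvectors then rotate arbitrarily inside the shared signal plane;
the discriminant direction is invariant to that rotation and reduces to the
single component whenever one component carries the axis alone.  PC1 is
never a default for scoring, as it often captures sample-specific variance.

## Synthetic cohorts

The generator emulates a multi-entity cell-line methylome study:

- **Baseline** — per-probe targets from a bimodal mixture (modes 0.1/0.9,
  jitter SD 0.04), shared by all groups, matching the U-shaped beta
  distribution of real methylomes.
- **Planted signal** — two axes (tissue lineage; differentiation program).
  Planted CpGs are blocks of ~4 adjacent clean probes with block-coherent
  direction, so DMR-scale structure exists; one side of each axis is
  shifted by `effect_delta_beta` (default 0.3).  Manifest positions cluster
  around island loci (islands ±400 bp, shores 0.6–2 kb, shelves 2–4 kb,
  open sea uniform), so inter-probe gaps resemble an array's.
- **Noise** — per-sample betas drawn from a Beta distribution with the
  target mean and SD `noise_sd` (default 0.05, a typical cell-line array
  scale), clipped to [1e-6, 1−1e-6].  Optional per-(group, probe) offsets
  (`entity_noise_sd`, default 0) add entity-specific variation; the default
  is zero so that non-planted probes are exactly null across groups.
- **Detection failures** — independent per (probe, sample) at rate 0.001.

What the generator does **not** emulate: raw intensity/dye effects, batch
structure, probe-type chemistry differences, correlated noise between
neighbouring probes, and realistic linkage between annotation categories
and methylation level.  Passing tests therefore demonstrate correctness of
the statistical machinery under a clean generative model, not performance
on real arrays.

## Problem sizes and numerical choices

The test and acceptance runs use scaled-down cohorts chosen to exercise
every stage while completing in minutes on one core: 20,000 probes with
8 samples/entity and 200 planted CpGs per axis for score recovery (three
seeds); 5,000 probes × 6 vs 6 over 20 seeds for null calibration; 12,000
probes for the differential/enrichment chain; 200 nested simulations of
n = 500 sets for bootstrap coverage.  Logit clipping uses ε = 1e-6; beta
offsets default to the conventional 100; all stage seeds derive from one
global seed via `SeedSequence` spawning, making every table byte-stable
under a fixed seed.

## Known limitations

- Two-group designs only; no covariate adjustment or >2-group contrasts.
- The Stouffer DMR statistic treats member CpGs as independent; spatially
  correlated noise would make region p-values anti-conservative.
- The moderated t is mildly conservative on logit-Beta noise at very small
  group sizes (measured ~0.009 at a nominal 0.01 with n = 6 + 6), a
  property of the noise model rather than the implementation (Gaussian
  nulls calibrate to 0.0098).
- Odds-ratio CIs use the Woolf approximation; very sparse tables are
  reported but their CIs are wide and approximate.
- Functional normalisation, cross-array merging and GO enrichment are out
  of scope; the pipeline consumes signals or betas that are already
  normalised.
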