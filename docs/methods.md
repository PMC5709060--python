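# Methods

This note documents the statistical model behind `mutmeth`, the choices
made where the design was genuinely open, and what the synthetic-cohort
experiments do and do not demonstrate.

## Statistical kernel

**Rank-sum test.** All two-group comparisons use the Wilcoxon rank-sum
(Mann–Whitney) test. For pooled sizes n1+n2 ≤ 20 the null distribution
of the rank sum is enumerated exactly by dynamic programming over all
C(n1+n2, n1) group assignments, with midranks under ties (doubled ranks
keep the arithmetic integral); the two-sided p is twice the smaller
tail, capped at 1. Larger samples use the normal approximation with tie
correction and continuity correction (scipy's `mannwhitneyu`). The
threshold 20 bounds enumeration cost while covering the smallest
testable groups (5 mutated samples). The matrix variant used by the
genome-wide scans applies the same dispatch: exact per row when the
pooled size permits, otherwise a single vectorized asymptotic pass.
Rows constant across both groups carry no evidence and get p = 1.

**Direction and effect.** Every comparison reports the sign of
median(group1) − median(group2) and the median difference itself, in
the tested variable's units. A positive direction always means the
mutated (first) group sits higher — on a probe's beta, a PC coordinate,
or an index. Exact ties give direction 0.

**Multiple testing.** q-values are Benjamini–Hochberg step-up
(statsmodels), chosen over π0-estimating variants for being
deterministic and assumption-light; BH guarantees q ≥ p, which several
table invariants rely on. The family is always stated: all gene × PC
tests of a cohort, all gene × probe pairs, all links, each one-sided
direction separately for aberrant calling, or a single gene's probes in
the re-correction variant.

**Correlations and enrichment.** Spearman via rank transform with the
t-approximation p (scipy); pairs with a missing member are dropped and
constant vectors are an explicit error (undefined correlation).
Pearson with the t distribution on n−2 df. Gene-set enrichment is the
hypergeometric upper tail P(X ≥ hits) on the draw/set/universe counts,
with sets first intersected with the analysis universe (all genes with
at least one analyzed link).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not array chemistry. Defaults define the study conditions used
throughout the experiments: 100 tumors, 30 adjacent normals, 5,000
probes (2,000 CGI / 1,500 SS / 1,500 open sea), subset baseline betas
0.15 / 0.5 / 0.8, and noise giving roughly 0.1 SD on the beta scale at
baseline.

* **Beta model.** Per probe, a logit-scale center (subset baseline plus
  N(0, 0.3) probe-level jitter) with Gaussian logit-scale noise, mapped
  through the inverse logit. This keeps betas inside (0, 1) and
  compresses variance near the boundaries as array betas do. The
  subset center is calibrated by numeric inversion so the *expected*
  beta equals the configured baseline despite the transform's skew.
  The logit noise SD is set by the delta method (sd/b(1−b)) to hit the
  target beta-scale SD at the baseline.
* **Planted effects.** A planted Δβ is the target difference in
  expected beta between mutated and non-mutated tumors; the
  corresponding logit shift is found per probe by Brent root-finding
  against a Gauss–Hermite quadrature of the logit-normal mean. Effects
  from several genes on one probe add on the logit scale.
* **Mutations.** Independent Bernoulli per gene, except genes sharing
  an exclusivity group, which are drawn per sample from one categorical
  distribution so that no sample ever carries two of them (frequencies
  summing above 1 are rejected).
* **Expression.** log2-RSEM-scale baseline 8.0 with Gaussian noise;
  a coupled gene adds slope × sign × (beta − subset baseline) from its
  partner probe, in every sample. Zero expression noise makes the
  coupling a strictly monotone map, so Spearman rho is exactly ±1 — a
  useful exactness check.
* **Seeding.** One integer seed; per-stage substreams derive from
  `numpy.random.SeedSequence.spawn`, so any stage's draw is independent
  of the others and the whole cohort is bit-reproducible.

What the generator does **not** model: probe type I/II chemistry and
BMIQ normalization, copy-number and tumor-purity mixtures, spatial
correlation along chromosomes, batch effects, and realistic outlier
tails. Passing recovery tests therefore shows the pipeline's logic and
error control are sound under its stated assumptions, not that real
cohorts meet those assumptions.

## Stage-specific choices

* **Probe filtering.** Exclusion lists (cross-reactive, SNP-adjacent,
  sex chromosomes) enter as annotation flags — the published lists are
  inputs, not shipped data. Removal reasons use a fixed priority (sex >
  cross-reactive > SNP > missingness) so a probe matching several is
  reported deterministically. The ≥ 90% missingness rule counts tumors
  and normals jointly and is inclusive at the threshold.
* **Aberrant calling.** One-sided tests per direction, BH within each
  direction separately; a probe is hyper when q < α and the tumor
  median exceeds the normal median (symmetrically hypo), making the two
  calls mutually exclusive. Cohorts without normals return an explicit
  uncallable table rather than an error, since downstream strata simply
  skip the hyper/hypo split.
* **PCA.** Fit on tumors only; probes centered, not scaled (betas share
  one scale). Missing cells are mean-imputed per probe — at the planted
  effect sizes and ≤ 90% missingness this changes no association call,
  which is why the heavier EM-style imputation was not implemented.
  Each component's sign is fixed so its largest-magnitude loading is
  positive; gene–PC p-values are invariant under sign flips, only the
  +/− extreme label moves. Default 5 components balances captured
  variance against the cost of the association layer; configurable.
* **HyperZ / HypoZ.** The indices are outlier fractions:
  z = (β − μ_normal)/max(σ_normal, 0.01) per probe, HyperZ = fraction
  of hyper-eligible probes with z > 2. Eligibility restricts hyper
  scoring to CGI probes normally below β 0.3 and hypo scoring to
  open-sea probes normally above 0.7, so the indices measure *aberrant*
  change against the normal reference. All five constants (z cutoff,
  two eligibility cutoffs, σ floor, and the subsets) are configuration.
  This fraction form is bounded in [0, 1], reads directly as "how many
  CGIs are aberrantly hypermethylated", and is robust to a few extreme
  probes; aggregating summed or averaged z is a reasonable alternative
  the index does not attempt to reproduce numerically.
* **Site scan.** One BH family per cohort over all gene × probe pairs.
  Probes missing in more than half of either group are skipped for that
  pair (a test-power floor). The empirical FDR permutes each gene's
  labels independently (preserving per-gene counts, breaking gene–probe
  linkage); a joint column-permutation mode preserving co-mutation
  structure is available. Ten full-scan permutations by default — the
  scan is the costly unit and the estimate is a mean of discovery
  counts, which stabilizes quickly.
* **Subtyping.** Ward linkage on Euclidean distances over the probe
  panel (variance-minimizing and standard for beta panels);
  (average, 1−Pearson) available as an option. k = 2 clusters by
  default with no automatic selection — the analysis reads the number
  of subtypes off the mutation structure, not the dendrogram. Panels
  are sorted by probe id and ties in the variance ranking break by id,
  making both panel selection and clustering order-invariant.
* **Integration.** "No change" in the four-category logic means "not
  significant at q < α in that group"; the supporting probe must be
  aberrant in the category's own group with the direction implied by
  the link's rho sign (hyper with positive rho supports up, hyper with
  negative rho supports down, etc.) and none-or-opposite in the other
  group. When a gene qualifies for categories in both groups (opposite
  moves in A and B), the larger expression effect wins — this keeps
  categories mutually exclusive and the A↔B swap an exact mirror.
  "At least double the normals" is a median log2 difference > 1.0; the
  highly-transcribed level cutoff is 10 log2 RSEM. An optional second
  reference gate additionally requires the expression change against
  non-mutated tumors, for single-gene (TP53-style) variants.

## Experiment sizes and numerical notes

The packaged experiments (`mutmeth.experiments`) run 20 replicates per
property at the default cohort size; the full set completes in a few
minutes on one CPU. Problem sizes are chosen so each property is
measured with adequate power while the suite stays fast: 95,000 tests
per null scan for FDR control, 50 planted probes at Δβ = 0.3 and
frequency 0.3 for recovery (sensitivity ≥ 0.8, precision ≥ 0.9),
disjoint 200-probe panels for subtype recovery (ARI ≥ 0.9), and 20
coupled genes across the four categories for integration.

Degenerate inputs are contracts, not crashes: identical groups give
p = 1 with direction 0; a zero-variance stratum, an empty universe, an
uncomputable index (fewer than two normals), or a fully-mutated gene
each produce a typed error, an explicit marker, or a warned skip as
documented on the operation.

## Known limitations

BH q-domination between nested families (single-gene vs joint
correction) is asserted only away from the q ≈ 1 tail, where rank
shifts from filler p-values can exceed the family-size shrinkage by
epsilon. The exact rank-sum branch enumerates up to pooled size 20;
beyond that the continuity-corrected normal approximation is slightly
conservative for very unbalanced groups, which makes all reported FDRs
err on the safe side. The generator's independence across probes
understates the correlation of real methylomes, so realized
false-discovery proportions on real data may sit closer to the nominal
level than the synthetic estimates suggest.
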