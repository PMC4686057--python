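# Methods

`fibrodiff` re-implements, as a tested and reusable pipeline, the
computational analysis of a four-arm fibroblast transcriptome study design:
patient (P) and control (C) dermal fibroblast lines, each cultured with and
without ascorbic acid (P_AA, C_AA), six lines per arm, profiled on a
log2-scale normalized (RMA-style) expression matrix. This note documents the
statistical models, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Rank-product differential expression

For a contrast with n1 numerator and n2 denominator samples, the all-pairs
matrix of log2 ratios is formed (n1·n2 columns; column (i, j) is numerator
sample i minus denominator sample j). Within each column genes are ranked —
descending for up-regulation, ascending for down-regulation, ties receiving
average ranks — and the rank product of a gene is the geometric mean of its
ranks across columns. A small RP marks a gene consistently near the top: the
statistic is non-parametric and invariant under any monotone transformation
applied to a whole column.

Significance is the permutation-estimated proportion of false positives
(pfp). For each permutation the group assignment is randomized, null rank
products are computed for every gene, and for each observed RP

    pfp = E[number of null RPs <= observed RP] / rank of the gene by RP,

made monotone non-decreasing along the RP-sorted list by a cumulative
maximum from the top. pfp is stored unclipped (values above 1 are
diagnostic) and clipped at 1 in written tables. Up- and down-regulation are
tested separately; a probe below the threshold in both directions — possible
only in pathological inputs — is assigned to the direction with the smaller
pfp. The significance threshold is strict (`pfp < 0.05`, not `<=`).

### Choice of permutation null

Because the n1·n2 ratio columns reuse the same n1+n2 values, a gene's ranks
are strongly coupled across columns, and the choice of null matters more
than in the one-sample (paired-ratio) formulation:

* **Shared label permutation (default, `scheme="labels"`).** One random
  bipartition of the pooled samples per permutation, applied to all genes.
  This preserves both the within-gene column coupling and the gene–gene
  correlation structure, so under no group difference the null RP
  distribution equals the observed one. On planted data (log2FC 2, noise SD
  0.5, six per group) it recovers >95% of regulated genes at pfp < 0.05 with
  a realized false-discovery proportion of ~0, and calls essentially nothing
  on pure noise.
* **Per-gene bipartitions (`scheme="within-gene"`).** Each gene's pooled
  values are independently re-bipartitioned (uniformly over the
  C(n1+n2, n1) splits, with a canonical ascending order within each side so
  that sampling converges to the exhaustive enumeration over per-gene
  splits). This null is exhaustively enumerable on small instances, which is
  how the sampled estimator is validated, but it is extremely conservative
  for detection: a strongly regulated gene re-creates its own extreme split
  with probability 2/C(n1+n2, n1) (≈ 1/462 at 6 vs 6), so with G genes the
  expected null count at the top of the list is about G/462 and the best
  gene's pfp plateaus near 0.5 regardless of effect size. It is therefore
  not the default.
* Plain rank randomization (independent uniform ranks per column) was also
  evaluated and rejected: it ignores the column coupling entirely, and on
  pure noise it calls ~25% of genes at pfp < 0.05.

In both available schemes the drawn first side of the bipartition is
attached to the study-order-first group of the contrast rather than to the
numerator, which makes swapping numerator and denominator exchange the up
and down results exactly under the same random stream (a tested invariant).

Default `n_permutations` is 1000 with a mandatory explicit seed; the null
counts pool over genes, so the Monte-Carlo error of pfp near the 0.05
threshold is far below it already at a few hundred permutations. Genes with
missing values in a contrast's samples are excluded from that contrast
(ranking requires complete vectors) and the exclusion count is logged; genes
with zero variance are retained and simply rank mid-pack.

### Fold changes and gene-level collapsing

The signed fold change is 2^m for mean log2 ratio m, reported as the
negative reciprocal when below 1 (ratio 0.5 prints as −2.0), so values never
fall in the open interval (−1, 1) and m = 0 maps to +1. Probe-level calls
are collapsed to unique genes by keeping, per gene, the probe with the
smallest pfp; a gene with probes called in both directions takes the
direction of its best probe. Unannotated probes are dropped with a count.

## Differential correlation networks

For every unordered pair in a user-supplied gene panel, the Pearson
correlation and its two-sided p-value (exact under bivariate normality,
equivalent to the t transform R·sqrt((n−2)/(1−R²)) on n−2 df; p = 0 at
|R| = 1) are computed separately within the patient and the control arm.
An edge is significant in an arm when |R| > r_min **and** p < p_max
(defaults 0.8 and 0.005, applied conjunctively exactly as stated), and the
retained edges are classified: `patient_only`, `control_only`,
`shared_concordant` (both arms, same sign), `shared_discordant` (both arms,
opposite signs). The classes partition the retained edges, and relabelling
the arms swaps the `*_only` classes while fixing the shared ones (tested).

At six samples per arm, p < 0.005 already requires |R| ≳ 0.94, so the 0.8
magnitude threshold is not binding and per-pair detection power is modest
even for strong planted correlations (~55% at true R = 0.95). The builder
therefore accepts `pool_patient` / `pool_control` arguments to pool treated
and untreated samples into each arm (12 per arm), under which a true R of
0.95 is detected with ~99% probability; the pooled configuration is what the
synthetic end-to-end run and the recovery checks use. Both thresholds and
the pooling are configurable. Missing values are deleted pairwise, with the
pair-specific n used in the test.

The same machinery drives the phenotype screen (|R| > 0.7, p < 0.05 by
default) over a sample-by-variable table; |R| = 1 pairs are retained but
flagged degenerate, since they usually indicate duplicated variables, and
variables with fewer than three observations are dropped with a warning.
The magnitude threshold is applied to |R| — negative correlations beyond
the threshold are retained.

## Ascorbic-acid reversion detection

A gene "reverts" when the treatment response undoes the disease effect: it
must be significant (pfp below the same 0.05 threshold) in **both** the
disease contrast (P−C) and the treatment-response contrast (P_AA−P), with
fold changes of opposite sign. Significance-in-both is an inferred
membership rule — every listed gene in the published style of reversion
table appears in both DE analyses — and is stated here as an assumption. No
fold-change magnitude filter is applied: reverted genes with |FC| below 1.5
are legitimate members. Output is sorted by disease-contrast direction
(up-in-disease first) and |FC| descending within each direction, and the
sign-flip invariant is asserted on every output row. No
closeness-to-control criterion beyond the sign flip is imposed.

## ΔΔCT quantification

Technical replicates are averaged on the CT scale. Per sample,
ΔCT = CT_target − CT_reference; ΔΔCT subtracts the mean control ΔCT, and the
per-sample relative expression is 2^−ΔΔCT. The group fold change is the
arithmetic mean of the per-sample values (the geometric mean — statistically
cleaner because 2^−ΔΔCT is log-normal under Gaussian CT noise — is available
via `mean="geometric"`), converted to the reciprocal sign convention, with
the SEM of the per-sample values reported. Two invariances hold by
construction and are tested: adding a plate offset to every CT leaves all
fold changes unchanged, and the control group's geometric-mean fold change
is exactly 1. The significance call |FC| > 1.5 is strict: 1.5 exactly is
not significant. Amplification-efficiency correction is out of scope.

## Over-representation analysis

A transparent one-sided hypergeometric test of a query list against GMT
gene-set collections over a user-supplied universe, which defaults to the
annotated genes on the analyzed matrix (array-background logic) rather than
the genome. The EASE variant removes one gene from the overlap before
taking the tail. Benjamini–Hochberg adjustment is applied across all tested
sets. This module is deliberately generic: it makes no attempt to reproduce
the scores of any versioned annotation-database tool, and its validation is
property-based (exact tail sums, BH hand examples, null calibration).

## Synthetic data generator

The generator emulates the study design so that every stage can be verified
against planted truth without external downloads:

* **Baseline**: one per-gene level shared across groups, N(8, 1.5²) on the
  log2 scale — typical of RMA summaries — so any group difference is
  attributable to a planted effect.
* **DE genes** (`de_fraction`, default 0.03 ≈ 600 genes at the 20,000-gene
  default, matching the scale of the disease signature): shifted by
  ±`de_log2fc` (default 2.0) in both patient arms. The effect-size
  distribution of real regulated genes is unknown; a single magnitude is a
  convention chosen for interpretable recovery rates, not an estimate.
* **Reversion genes** (default 40): shifted in P only, so the fold change
  flips sign between P−C and P_AA−P while C_AA stays at control level, and
  the magnitude equals `de_log2fc` in both contrasts, making membership in
  the planted set decidable.
* **Correlation modules**: one latent factor per module; member genes load
  with magnitude sqrt(r) in the groups where the module is active, giving
  pairwise correlations of exactly ±r. A group sign of −1 flips the loading
  of odd-indexed members, planting sign-flipped (discordant) pairs. The
  factor-structured part replaces — rather than adds to — the noise term, so
  the marginal SD stays `noise_sd` and the planted correlation is exact
  regardless of the noise level.
* **Noise**: i.i.d. Gaussian, SD 0.5 by default (log2 units), a realistic
  residual scale for cell-line replicates. Zero noise is allowed and yields
  the deterministic limits used by several tests.
* **Reproducibility**: a single seed drives a fixed stream-splitting order
  (baseline → category assignment → module factors → noise), so identical
  configurations are bit-identical and partial configuration changes
  perturb only downstream streams.

CT tables are generated so that the expected 2^−ΔΔCT equals the requested
fold change; phenotype tables are multivariate normal with the requested
pair correlations (infeasible joint specifications are rejected via the
Cholesky factorization).

What the generator does **not** emulate: probe-level (CEL) intensities and
RMA itself, batch or culture-passage effects, heavy-tailed or
intensity-dependent noise, correlated effect sizes, and annotation
ambiguity beyond simple many-to-one probe maps. Passing recovery tests
therefore demonstrate correctness of the statistics under the stated
generative model, not robustness to every artifact of real microarray data.

## Problem sizes used in the validation suite

The test suite and the acceptance script run the generator at reduced gene
counts (400–1000 genes; the generator default is 20,000) and 100–200
permutations (package default 1000). These sizes were chosen so the pooled
null keeps the pfp Monte-Carlo error far below the 0.05 threshold (the null
counts pool G·P draws) while the whole validation runs on a single CPU in
well under an hour; the recovery rates reported are insensitive to the gene
count because sensitivity and false-discovery control are per-gene
properties at fixed group size.

## Numerical choices and degenerate inputs

* Ties in ranking receive average ranks (deterministic and symmetric).
* pfp monotonicity is enforced by cumulative maximum from the top-ranked
  gene; ranks for the E/rank denominator use the ties-take-max convention.
* Expression matrices are written losslessly (`%.17g`); derived tables use
  4 decimals, matching the style of published result tables.
* Gene symbols are matched exactly after uppercasing and whitespace
  trimming; no alias resolution is attempted.
* Empty networks, empty gene lists and empty contrast results are valid and
  produce valid empty documents.
* The exact analytic Pearson p and an exact permutation p necessarily
  disagree at very small n (the permutation test conditions on the sample
  and has 1/n!-level granularity); the validation asserts agreement on
  average rather than per draw.

## Known limitations

* The pfp ("FDR") is the rank-products permutation estimate, not a
  Benjamini–Hochberg value; the two are used interchangeably in the field's
  tables but differ in definition.
* The network stage applies no multiple-testing correction across pairs, by
  design — edge thresholds are conjunctive point criteria.
* Reproducing published per-dataset counts requires the original deposited
  matrix; this package validates the machinery on planted-truth synthetic
  studies and accepts any tab-delimited or series-matrix input for
  re-analysis.
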