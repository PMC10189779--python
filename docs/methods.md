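# Methods

## Setting and model

All estimators operate on GWAS summary statistics: for each SNP j and each
phenotype, a per-allele additive effect estimate β̂ⱼ with standard error seⱼ,
the effect-allele frequency, a p-value and the GWAS sample size.  Binary
phenotypes are handled on the log-odds scale throughout.  The two-sample
assumption is that exposure and outcome panels come from non-overlapping
samples of the same ancestry, so sampling errors are independent across
panels.

A SNP is a valid instrument for an exposure when it is associated with the
exposure, shares no confounder with the outcome, and affects the outcome
only through the exposure.  Every sensitivity tool in the package targets
failures of the third (exclusion-restriction) assumption.

## Harmonization

Effect alleles are aligned to the exposure panel per SNP: identical allele
pairs are kept, swapped pairs flip the sign of β and replace EAF by 1−EAF,
strand-complement pairs are complemented.  For palindromic SNPs (A/T, C/G)
allele letters cannot distinguish a swap from a strand flip, so alignment
uses which side of 0.5 each panel's EAF falls on; SNPs whose EAF lies inside
the configurable ambiguity band (default [0.42, 0.58]) in any panel, or is
missing, are dropped.  Harmonization is idempotent and every action is
logged per SNP.  Records with missing EAF are kept for estimation but
excluded from variance-explained computations.

## Instruments

Defaults follow standard two-sample MR practice: p < 5×10⁻⁸ (strict
inequality), MAF ≥ 0.01, greedy clumping at r² ≤ 0.001 against a supplied
LD matrix (smallest p-value wins; ties break lexicographically on SNP id
for determinism).  No genomic positions are carried, so the kb window is
not applied; all pairs present in the matrix are eligible.  Per-SNP
variance explained is R² = 2β²·EAF·(1−EAF)/SD², with SD defaulting to 1
(standardized phenotype).  The aggregate F statistic
((N−k−1)/k)·(R²/(1−R²)) uses the summed R² and the median per-SNP N, and
drives the F > 10 weak-instrument gate; per-SNP F values (k = 1) are also
reported because the gate is sometimes applied per variant.

## Univariable estimators

* **IVW**: weighted regression of β_Y on β_X through the origin with
  weights 1/se_Y²; identical to the inverse-variance-weighted mean of the
  Wald ratios.  The default is the multiplicative random-effects model,
  which inflates the fixed-effects SE by max(1, √(Q/(k−1))) — conservative
  under heterogeneity, identical to fixed-effects when Q ≤ k−1.  P-values
  are normal.
* **MR-Egger**: the same regression with a free intercept after orienting
  all exposure betas non-negative.  The slope is the causal estimate, the
  intercept the average directional pleiotropy.  SEs carry the same
  max(1, σ) inflation; inference uses t with k−2 df.
* **Weighted median**: Wald ratios ordered, weighted by their inverse
  first-order variance β_X²/se_Y²; the estimate is where the cumulative
  weight crosses 0.5, linearly interpolated.  The SE is a seeded parametric
  bootstrap (default 1000 replicates) redrawing (β_X, β_Y) from their
  sampling normals; the seed and replicate count are recorded in the
  output.
* **Contamination mixture**: each ratio is modelled as valid,
  N(θ, se_r²), or invalid, N(0, se_r² + ψ²); the profile log-likelihood at
  each of 1000 grid points (spanning the ratio range ± 3 SD) takes the
  better classification per SNP.  ψ defaults to 1.5× the SD of the ratio
  estimates.  The mixture uses second-order ratio variances (including the
  exposure-error term): with weaker instruments the first-order variance
  understates the ratio spread and inflates spurious invalid calls.  The
  95% CI is the 2-unit profile log-likelihood drop region; the grid raises
  an error if the maximum lands on its boundary.

Equivariance holds exactly for all estimators: rescaling exposure betas by
c > 0 divides estimates by c, and negating outcome betas negates them.

## Sensitivity battery and decision rule

Cochran's Q is the weighted squared dispersion of the ratios around the
fixed-effects IVW estimate (first-order weights), referred to χ²(k−1).
MR-PRESSO compares the observed weighted leave-one-out residual sum of
squares with parametric simulations under no pleiotropy; per-SNP outliers
use a Bonferroni threshold α/k; empirical p-values are
(1 + exceedances)/(n_sim + 1), so the floor at the default n_sim = 1000 is
1/1001.  When outliers are found, IVW is recomputed without them and a
distortion test compares the change against random same-size removals.

The reported estimate follows a fixed rule at α = 0.05 (configurable) for
both gates: no heterogeneity and no pleiotropy → IVW; heterogeneity with
concordant IVW/weighted-median direction → weighted median; pleiotropy →
outlier-corrected IVW (plain IVW when no outliers are identified, flagged);
heterogeneity with discordant directions → IVW flagged "discordant" rather
than suppressed.

## Multivariable MR and classification

Instruments are pooled as the union of each exposure's selected SNPs,
re-harmonized across all panels with complete-case dropping.  Outcome betas
are regressed on the m exposure-beta columns without intercept, weights
1/se_Y², SEs inflated by max(1, σ) as in univariable IVW; with m = 1 the
two coincide exactly.  A rank-deficient exposure matrix raises an error
naming the collinear exposures.  A univariably significant exposure is
classified *independent* iff its conditional p-value is strictly below the
classification α, which defaults to the study's Bonferroni threshold.

## Mediation

For exposure X and mediators M₁..M_K: β1ₖ is the univariable IVW effect of
X on Mₖ (X's instruments); β2ₖ the coefficient of Mₖ in a pairwise
(X, Mₖ) → Y multivariable fit; β3 the coefficient of X in a multivariable
fit adjusted for the whole mediator subset.  The proportion mediated is

E (%) = 100 · Σₖ β1ₖβ2ₖ / (β3 + Σₖ β1ₖβ2ₖ),

i.e. indirect / (direct + indirect); the denominator groups β3 outside the
sum, the only reading consistent with reporting single-mediator
percentages next to singly adjusted odds ratios.  The SE is the first-order
delta method with a diagonal covariance (mediators and coefficients treated
as independent), gradient computed analytically; a Monte-Carlo propagation
mode cross-checks it.  E and its CI may fall outside [0, 100] and are never
truncated, and the joint-mediator E need not equal the sum of
single-mediator Es.

## Study pipeline

Stage 1 screens each exposure × outcome pair and gates significance of the
*decided* estimate at α_family/n_comparisons (default 0.05/6 = 8.33×10⁻³,
displayed to 3 significant figures).  Stage 2 runs multivariable MR per
outcome on the survivors and partitions them independent/mediated.  Stage 3
treats each mediated survivor as an exposure and every other survivor as a
candidate mediator, singly and jointly.  Stages with empty inputs are
skipped with a logged note.  Everything is deterministic given the study
seed (per-pair seeds are spawned in sorted order).

## Synthetic generator

Summary statistics are generated directly on the summary scale, without
individual-level genotypes.  Each trait owns a set of instrument SNPs with
effects γⱼ drawn uniformly in magnitude from [0.015, 0.08] with random sign
(large enough to clear genome-wide significance at the emulated sample
sizes, with a tail of weak instruments); effects on downstream traits are
summed path products through the configured DAG; a configurable fraction of
instruments get a pleiotropic outcome effect (balanced: zero-mean;
directional: mean = the pleiotropy scale).  Standard errors follow
se = 1/√(2·N·EAF·(1−EAF)) with EAF uniform on [0.05, 0.95]; the binary
outcome uses the same form on the log-odds scale.  Panels re-present
alleles swapped and/or strand-complemented at random so harmonization is
genuinely exercised; noise is independent across panels (no sample
overlap).  The default study scenario has four exposures (two direct at
log-OR ±0.45, two acting only through them), 150 instruments per trait
(within the emulated 14–507 range), exposure GWAS of 0.4–1.2 million
samples and an outcome of 11,348 cases and 15,861 controls (27,209
subjects).

What the generator does **not** emulate: real LD structure (blocks are
synthetic and supplied separately), population stratification, winner's
curse, sample overlap, and — because binary-outcome effects are simulated
directly on the log-odds scale rather than through a logistic model — the
noncollapsibility of odds ratios.  Passing tests therefore validate the
estimation machinery under its own assumptions, not the behavior of
OR-scale mediation proportions on real case-control data, where
noncollapsibility can bias mediated proportions.

## Validation scenarios and problem sizes

The validation battery (`mrchain.validation`, shared by the test suite and
`scripts/acceptance.py`) uses these sizes, chosen as the package's own
standard experiment set: CI coverage over 1000 replicates of the default
two-trait scenario; Cochran's Q size over 2000 homogeneous-null replicates
at zero causal effect (with a nonzero effect and noisy exposure betas the
first-order-weight Q is intrinsically anticonservative — about 7% size at
effect 0.4 in these conditions — a property of the statistic that users
should know); weighted-median robustness with 30 instruments, 40%
directional contamination shifting ratios by ~0.5 (the bias/SE of the
median grows like √k under one-sided contamination, so the contrast with
IVW is sharpest at moderate k); MR-PRESSO sensitivity with one planted
+1.0-ratio outlier among 30 strong instruments over 200 replicates at
n_sim = 1000; mediation recovery on a fully mediated chain with a
100k/100k-case-control outcome so the proportion is tightly determined;
and 100 full-study replicates for the partition recovery rate.

## Known limitations

* The contamination-mixture profile CI is slightly anticonservative here:
  measured null coverage is ~91–93% under the default conditions (the hard
  valid/invalid classification absorbs tail ratios and narrows the
  profile), and with a causal effect far from zero its zero-centered
  invalid component absorbs the low ratio tail asymmetrically, giving a
  small upward bias when instrument precision is heterogeneous.  Treat it
  as a supplementary estimator, as the decision rule does.
* Cochran's Q and the ratio weights ignore exposure-side noise to first
  order; both are mildly anticonservative with many weak instruments.
* Mediation SEs assume uncorrelated coefficient estimates; overlapping
  instrument sets across mediators violate this mildly.
* Clumping requires an externally supplied r² matrix; no reference-panel
  LD computation, proxy lookup, VCF parsing or catalog access is provided.
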