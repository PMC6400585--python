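# Methods

This note documents the models, the synthetic-data generators, the numerical
choices and the known limitations of `prs_atlas`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Score construction

Scores are weighted allele counts, `S_i = sum_j w_j g_ij`, with weights equal
to reported GWAS per-allele coefficients (or their signs for unweighted
scores, used when the weight source overlaps the target cohort and
overfitting is a concern). Candidate SNPs pass a p-value threshold — both
5e-5 (the lenient atlas threshold, chosen to capture sub-genome-wide-significant
signal) and 5e-8 (the conventional threshold, used for MR instruments) are
first-class settings — and are then greedily clumped: rank by ascending p,
accept the best, discard everything within the window (default 10,000 kb)
with panel r² ≥ the threshold (default 0.001), repeat. Ties on p break by
chromosome, then position, then id, which makes clumping independent of
input row order; the window default follows common summary-statistics
practice since only the r² threshold is a principled choice.

A SNP absent from the target genotypes may be replaced by the panel SNP in
strongest LD, requiring r² ≥ 0.8; if the proxy's counted allele is
negatively correlated with the target's effect allele, the weight's sign is
flipped. Allele harmonisation between the GWAS and the target coding
resolves plain swaps (negate the weight), strand flips (complement), and
palindromic A/T and C/G pairs by frequency concordance; palindromic SNPs
whose effect-allele frequency falls in [0.42, 0.58] on either side are
dropped as unresolvable. Missing hard calls contribute the SNP's cohort-mean
dosage (keeping n constant); dropping such individuals instead is available
by flag. Raw scores are standardised to mean 0, SD 1 with the n−1
denominator; combined scores are sums of standardised scores,
re-standardised.

## Phenome scan

Each score–trait pair is fitted with the family-appropriate likelihood:
ordinary least squares (continuous), logistic (binary), proportional-odds
logistic on a latent logistic variable (ordinal), multinomial logit
(categorical), all adjusted by default for age, sex, ten principal
components and a chip indicator. Effects are per SD of the score, so they
are invariant to affine rescaling of the raw score. Sex-restricted traits
keep only females (coded `sex == 0` by the cohort generator) and drop the
sex covariate.

Variance explained is recomputed without covariates: R² for continuous
traits and McFadden's pseudo-R², `1 − ln L_m / ln L_0`, otherwise, with
`L_m` the score-only and `L_0` the intercept-only likelihood. For
categorical traits the headline p-value is the likelihood-ratio test of the
score's `K−1` coefficients against the covariate-only model, and the
reported effect is the level with the largest |z| — a single-p convention
the scan needs for its signed −log10(p) column, whose sign follows that
effect. Fits that fail or do not converge are flagged and retained so row
counts stay auditable; pairs with fewer than 50 complete cases are skipped
with a reason. The multiplicity threshold is 0.05 divided by the number of
executed tests.

Decile contrasts split the standardised score at the nine type-7 empirical
quantiles with boundary ties to the lower decile; with no covariates the
top-versus-bottom odds ratio is the 2×2 contingency OR, with the
Haldane–Anscombe 0.5 correction (and a flag) on a zero cell. AUC is the
Mann–Whitney rank statistic (ties count one half); the ROC curve is swept
over every distinct predictor value, and trapezoidal integration of that
curve reproduces the rank AUC exactly.

## Two-sample MR

Instruments are the exposure's clumped SNPs at p < 5e-8 (weak-instrument
avoidance), harmonised to the outcome study with the same allele rules as
scoring. With per-SNP exposure effects γ_j (SE σ_γj) and outcome effects
Γ_j (SE σ_Γj):

* **Wald ratio** (single SNP): Γ/γ, SE σ_Γ/|γ| (first order).
* **IVW**: weighted regression of Γ on γ through the origin with weights
  1/σ_Γ², i.e. `Σ γΓ/σ_Γ² / Σ γ²/σ_Γ²`; fixed-effect SE
  `sqrt(1/Σ γ²/σ_Γ²)`. Cochran's Q is `Σ w_j (β_j − β̂)²` over the Wald
  ratios with `w_j = γ_j²/σ_Γj²`, referred to χ²(J−1). The
  multiplicative-random-effects SE multiplies the fixed SE by
  `max(1, sqrt(Q/(J−1)))` and is the default of `mr.ivw`; because the floor
  only ever inflates, this variant is mildly conservative when instruments
  are homogeneous, which is why the triage's step 1 and the power study use
  the plain fixed-effect form (heterogeneity there is surfaced by Q and
  handled by the later steps, not folded into the first-step SE).
* **MR-Egger**: the same weighted regression with a free intercept after
  orienting every SNP so γ_j ≥ 0 (negating γ and Γ jointly); the slope is
  the causal estimate and the intercept the average directional pleiotropic
  effect. SEs carry a `max(1, residual scale)` inflation; p-values use t
  with J−2 df.
* **Weighted median**: Wald ratios ordered ascending with normalised
  weights `w_j = γ_j²/σ_Γj²`; the estimate interpolates where the midpoint
  cumulative weight `S_j = Σ_{i≤j} w_i − w_j/2` crosses one half. SE by
  parametric bootstrap (γ_j, Γ_j resampled from normals at their SEs,
  seeded, 1000 draws by default).
* **Weighted mode**: argmax on a 512-point grid of a weighted Gaussian
  kernel density over the ratios, bandwidth
  `φ · 0.9 · min(sd, IQR/1.349) · J^(−1/5)` (φ = 1 by default); identical
  ratios short-circuit to the common value with SE 0. Bootstrap SE as for
  the median.
* **Steiger filtering**: per SNP, variance explained is recovered from the
  t statistic, `r² = t²/(t² + n − 2)`, on each side; a SNP is kept iff it
  explains more variance in the exposure than in the outcome. The t-to-r²
  conversion treats binary outcomes on the observed scale; liability-scale
  conversions are out of scope.
* **Leave-one-out**: IVW re-estimated J times dropping one SNP, flagging
  sign changes and p-values crossing α.

All estimators are invariant to jointly flipping the signs of any SNP's
(γ, Γ) pair, and all reduce to the Wald ratio at J = 1 (median and mode via
an explicit non-strict fallback).

## Decision frameworks

The triage encodes a three-step screen with a configurable α (default
0.05): (1) fixed-effect IVW with Q — weak evidence ⇒ NOT_SUPPORTED; (2)
when Q_p < α, the weighted median *and* mode must be re-examined — neither
supporting ⇒ NOT_ROBUST (when Q is quiet the step still runs, advisorily;
a flag makes it always binding); (3) the Egger intercept is tested on the
full instrument set and IVW is re-run on the Steiger-filtered set — an
intercept p < α or a lost IVW signal ⇒ SENSITIVITY_FLAGGED, otherwise
CAUSAL_CANDIDATE. The intercept is deliberately tested *before* filtering:
directionality filtering tends to remove exactly the pleiotropic
instruments the intercept detects, so a filtered-set intercept test is
self-defeating.

Bi-directional MR runs the triage in both orientations with independently
selected instruments and labels the pair by which directions emerge as
clean candidates. Mediation MR multiplies the IVW estimates along an
ordered chain of exposures into an indirect effect (delta-method SE from
the relative SEs), estimates the total effect by IVW from the first
exposure to the outcome, and reports proportion mediated = indirect/total —
the form consistent with the worked 77% example; the printed-difference
variant (total − indirect)/total is available behind a flag. Zero totals
and sign-discordant indirect/total pairs are flagged rather than silently
reported. Multivariable MR regresses outcome effects on the matrix of all
exposures' effects (union of each exposure's clumped genome-wide-significant
SNPs, complete cases across studies, no intercept, weights 1/σ_Γ²), with a
rank check that names collinear exposures, and reports conditional
estimates alongside univariable IVW and their ratio (attenuation).

## Synthetic data

Genotypes are Binomial(2, p_j) hard calls with p_j ~ Uniform(maf_range)
(default 0.05–0.5). LD blocks share a latent haplotype pair: the first
member is the latent variable and each other member copies latent alleles
with probability sqrt(r²), so its squared correlation with the first member
is the requested r² (exact duplication at r² = 1); pairwise r² among
non-first members is approximately r⁴. Positions are evenly spaced 100 kb
apart so the clumping window logic is exercised.

The two-sample generator draws per-SNP exposure effects half-normal and
rescales them so the SNPs explain a target heritability (default 0.3) of a
unit-variance exposure. Coding effects positive makes the effect allele the
exposure-increasing allele, which is what renders *directional* pleiotropy
meaningful: a directional scenario draws the direct SNP-on-outcome effects
α_j ~ Normal(mean ≠ 0, sd) on a configurable fraction of SNPs, balanced
scenarios set the mean to zero. The outcome is
`y = β·x + Σ α_j g_j + e'`, and the exposure and outcome GWAS are marginal
per-SNP regressions in two disjoint samples (defaults 10,000 individuals,
50 SNPs). Cohorts add the covariate surrogates (age N(57, 8), sex, ten
standard-normal PC stand-ins, chip) and generate declared trait families
from linear predictors; confounding enters only through declared covariate
effects.

The mediation chain wires four traits X → M1 → M2 → Y, each with ten
private instruments explaining 10% of its variance, plus a configurable
direct X → Y path; four disjoint samples each yield one trait's GWAS over
the union of SNPs, so every edge is a genuine two-sample analysis. The
private-instrument variance is set so upstream SNPs generally fall short of
genome-wide significance two steps down the chain, keeping the edge
estimands clean; the recorded truth is
`proportion mediated = b1·b2·b3 / (b1·b2·b3 + direct)`.

What the generators do *not* emulate: realistic human LD maps, imputation
uncertainty, population structure beyond the PC-surrogate columns, sample
overlap between studies, case/control ascertainment in the GWAS inputs.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under its stated assumptions, not robustness to those
real-data complications.

## Power study

`run_comparison` replicates the two-sample generator across a grid of
pleiotropy fractions (default 0, 0.1, …, 0.5) under a causal (β = 0.3) and
a null (β = 0) model, 1000 replicates per cell, 10,000 individuals per
sample, 50 SNPs. The PRS arm clumps and weights a score from the discovery
GWAS at p < 5e-5, scores the disjoint outcome sample and t-tests the
outcome on the standardised score; the IVW arm instruments at p < 5e-8
(fixed-effect, Wald-ratio fallback at J = 1), with the Egger intercept
tracked as the pleiotropy detector. Rates are reported with binomial
Monte-Carlo SEs, and failed replicates are counted and excluded. Directional
pleiotropy defaults to α_j ~ N(0.05, 0.05²); the magnitudes are package
choices on the order of the per-SNP exposure effects, since the qualitative
contrast (score-based tests gain power but inherit pleiotropy as false
positives, which the MR sensitivity analyses surface) is the reproduction
target, not any specific curve.

## Problem sizes and tolerances

The test suite runs the calibration and triage-null cells at the full
1000-replicate, n = 10,000, m = 50 scale and keeps Monte-Carlo unit tests at
reduced sizes (200–400 replicates, n = 1000–20,000) chosen so each
assertion's Monte-Carlo SE is small against its tolerance; recovery
assertions use 3 MC SEs with a floor of 0.05 on proportions. Closed-form
identities (IVW vs explicit WLS, rank-AUC vs trapezoid) are asserted to
1e-10; exact arithmetic examples to machine precision. Bootstrap draws and
every simulation consume seeds threaded from a single generator, so all
results are reproducible bit for bit given a seed.

## Known limitations

* Instrument selection and effect estimation share the discovery sample, so
  weak-instrument winner's curse attenuates MR estimates when per-SNP F
  statistics are modest; the default settings keep instruments strong.
* The PRS arm of the power study is two-sample (weights from discovery,
  testing in the outcome sample); a one-sample variant would show additional
  overfitting not modelled here.
* McFadden pseudo-R² values are not comparable to linear-model R² and are
  reported without covariate adjustment by construction.
* Correlated-instrument MR, MR-PRESSO-style outlier removal, LD-aware
  weighting and cross-ancestry panels are out of scope.
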