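# Methods

## Functional effects and the reference point

`noiavar` uses the *functional* NOIA parameterization: every genetic effect
is a deviation from a fixed reference genotype, the line homozygous for the
reference allele at all loci. The index variables are the donor-allele
count Xa ∈ {0, 1, 2} and the heterozygosity indicator Xd ∈ {0, 1}, so the
reference genotype has an all-zero design row and the model intercept μ is
its genotypic value. Pairwise epistasis enters through the four products
Xa·Xa, Xa·Xd, Xd·Xa, Xd·Xd per modelled locus pair. Functional effects do
not depend on population allele frequencies, which is what makes the
downstream variance predictions possible for arbitrary frequencies.
Statistical-orthogonal parameterizations, and the F∞ / unweighted-regression
codings (which predict identical genotypic values from a different
reference point), are out of scope.

Locus pairs without interaction measurements are treated as having exactly
zero epistatic effects with zero sampling (co)variance, and interactions of
order three and higher are assumed absent. `EffectEstimates.aligned`
implements this: absent epistatic labels zero-fill; absent main-effect
labels raise.

## The mixed model

For one trait, Z = μ + Xb + cohort + family + ε with Gaussian random
intercepts for cohort and for seed family (an environmental maternal
effect, nested within multilocus genotype — enforced by composite family ×
genotype keying) and within-family residual ε. Traits are fitted
independently; rows with a missing trait value are dropped per trait.

Fitting is REML via statsmodels MixedLM. Two layouts are used:

* **nested** (default when every family occurs in a single cohort, as in
  nursery designs where a seed family is sown in one grow-up): cohort is
  the grouping factor, with a random intercept per cohort and family
  variance components within cohort. This is fast and numerically stable
  (n ≈ 10⁴ with 58 fixed effects fits in seconds).
* **crossed** (fallback): a single group containing all observations with
  variance components for both factors. Correct but much slower; only used
  when families genuinely cross cohorts.

The optimizer escalates bfgs → powell → Nelder–Mead before declaring
failure. Data that an OLS fit interpolates exactly (zero residual sum of
squares — e.g. noiseless simulations) are returned from the OLS path with a
zero covariance matrix, since REML is undefined there; `re_structure="none"`
forces that path for data simulated without grouping noise. The sampling
covariance S of the fixed effects is the model-based (expected-information)
covariance; no robust/sandwich option.

The overall test for epistasis compares the full fixed-effect structure
against the a/d-only structure *on the same observations* after ML refits
(REML likelihoods are not comparable across fixed-effect sets):
chi² = 2(ℓ_full − ℓ_reduced) with df equal to the number of interaction
columns (44 for 11 pairs). Parameter accounting follows the convention of
genetic-effect columns plus one cohort and one family term, intercept not
counted: 60 and 16 for the seven-locus/eleven-pair design.

The separate reduced fit to the single-segment subset (plants non-reference
at at most one locus, `scope="single_locus_only"`) is used only to define
*non-epistatic* genotypic values for the deviation summaries, not for the
LRT.

## From effects to variance components

Under Hardy–Weinberg proportions and linkage equilibrium, the multilocus
genotype distribution factorizes per locus as (q², 2pq, p²) over the
donor-allele counts (0, 1, 2). Random mating is assumed throughout; no
linkage-disequilibrium option.

* **Genotypic value.** Ẑ_G,u = μ + Σᵢ b̂ᵢ X_{i,u}; with the epistasis flag
  off, only a/d terms enter.
* **Total genetic variance.** V̂_G = E[Ẑ²] − E[Ẑ]² over the genotype
  distribution. Expectations of design-variable products factorize across
  loci: each column is a monomial in per-locus (Xa, Xd), and
  E[Xa^r Xd^s] = 2pq for s ≥ 1, 1 for r = s = 0, and 2pq + p²2^r
  otherwise. This gives an O(B²·L) evaluation; the exhaustive 3^L
  enumeration is retained as a backend and the two agree to 1e-10 (tested
  for L ≤ 4 over random draws).
* **Bias correction.** Since E[b̂ᵢb̂ₖ] = bᵢbₖ + s_{b̂ᵢb̂ₖ}, the corrected
  V_G subtracts the sampling (co)variance of every product of estimates in
  both E[Ẑ²] and E[Ẑ]². Algebraically the whole correction collapses to
  V_G* = V̂_G − Σᵢₖ s_{b̂ᵢb̂ₖ}·Cov(Xᵢ, Xₖ), so the intercept (whose design
  variable is constant) contributes nothing, as it must — a constant shift
  has no variance. An alternative form that subtracts the *product of
  standard deviations* s_{b̂ᵢ}s_{b̂ₖ} in the E[Ẑ]² term is available behind
  `eq13="sd_product"` for comparison; only the covariance form makes the
  corrected estimator mean-unbiased (verified by the Monte-Carlo study
  below), so it is the default.
* **Average effects.** α_k = α_{k,1} − α_{k,2} with α_{k,1} =
  p_k E[Z|WW] + q_k E[Z|Ww] and α_{k,2} = p_k E[Z|Ww] + q_k E[Z|ww],
  conditional means taken over the other loci's genotype distribution.
  α_k is a linear form c_kᵀb̂ (the coefficient vector is returned), so the
  corrected squared effect is (c_kᵀb̂)² − c_kᵀS c_k. Without epistasis
  α_k = a_k + d_k(q_k − p_k) independent of other loci. At p_k ∈ {0, 1}
  the conditional means remain defined and the 2p_kq_kα² contribution is 0.
* **Additive variance.** V_A = Σ_k 2p_kq_kα_k², summed from the per-locus
  contributions (corrected or not). From exact effects V_A equals the
  variance of the best linear allele-count predictor, hence V_A ≤ V_G;
  bias-corrected values can legitimately go negative when sampling error is
  large and are reported unclipped (with a logged warning), never truncated.

## Allele-frequency models

Frequencies are of the donor allele, independent across loci and sets.
Two samplers: uniform on [0, 1], and the neutral-theory U-shaped density
∝ 1/(p(1−p)) truncated to [ε, 1−ε], drawn by inverse CDF (the truncated
logit transform). ε defaults to 0.01 and is configurable because no
canonical value exists; the ensemble size used in the study-level summaries
is 200 sets. The built-in bootstrap scenarios fix every locus at reference
frequency q = 0.5 or q = 0.05 (donor p = 0.5 / 0.95).

## Synthetic data

The generator produces trait = genotypic value + cohort draw + family draw
+ residual, all Gaussian (the distributional assumption of the mixed
model). Two designs: *balanced* (one family of `n_per_cell` plants per
nine-class two-locus cell per cohort) and *mirror* (replicating the row,
cohort and family structure of a template table — the parametric-bootstrap
case).

`simulate_study_like` emulates a seven-QTL floral panel: 11 of the 21
possible pairs measured with all nine two-locus genotype classes, 12
cohorts with each pair grown in 3 of them, families per cohort × pair ×
class uniform on {2..5}, family sizes geometric with mean ≈ 10 truncated at
40. These family distributions are invented (chosen to mimic unbalanced
greenhouse replication) and calibrated once so the expected total is
≈ 10,500 records; the 11-pair subset is likewise a fixed synthetic choice.
Per-trait effect priors (a ~ N(0, 0.45²) etc. for corolla width in mm;
day-scale values for flowering time) and variance components are set to
medium-effect floral-QTL magnitudes. The generator does not emulate
genotyping error, plant removal, non-Gaussian tails, or linkage between
QTLs — passing tests demonstrate correctness of the estimation and
prediction machinery under the model's own assumptions, not robustness to
violations of them.

## Validation studies and the sizes used

* **Monte-Carlo unbiasedness** (2,000 draws): b̂ ~ N(b, S) with known S;
  mean corrected V_G and V_A match the truth within 3 Monte-Carlo standard
  errors while uncorrected means exceed it.
* **Parametric bootstrap** (200 replicates): a 3-locus, 3-pair truth with
  cohort/family/residual variances (0.3, 0.4, 2.5) on a balanced 6-cohort
  design (~486 plants); each replicate is simulated, refitted by REML, and
  mapped to corrected and uncorrected V_G/V_A at p = 0.5. Summaries are the
  standardized bias (x* − x)/x and standardized MSE Σ(est − x)²/(n·x²);
  the corrected estimator shows near-zero bias with no MSE penalty, and the
  corrected and uncorrected replicate distributions have nearly identical
  variances (the correction shifts location, not spread). Replicate seeds
  are spawned counter-style from the master seed so individual replicates
  can be re-run.
* **LRT calibration** (500 null datasets): the chi² reference for an ML
  likelihood-ratio test is asymptotic, and the relevant sample size is the
  number of *families*, not plants. Family-poor designs show the well-known
  anticonservatism of ML fixed-effect tests (we measured type-I rates of
  ~0.12 at 36 families falling monotonically toward nominal with more);
  the calibration study therefore uses 1,080 families (2 plants × 9 cells ×
  120 cohorts), the regime the real experimental scale (~10⁴ plants,
  hundreds of families) occupies, where the null mean of the statistic is
  4.0 for 4 df and the rejection rate is ~5%.
* **Acceptance script** sizes: study-like pipeline at `scale=0.25`
  (~2,600 plants) for the end-to-end fit, 200-set uniform ensembles, and a
  300-dataset LRT calibration; chosen so a full run completes in a few
  minutes on one CPU while keeping every Monte-Carlo standard error well
  inside the margins being tested.

## Numerical choices and edge cases

* Column order is deterministic (loci in declared order; pairs in
  declared-locus order; aa, ad, da, dd within a pair) so effect vectors and
  covariance matrices align across fits.
* Genotype input accepts donor-allele counts 0/1/2 or string codes
  ww/Ww/WW; unknown codes fail with the offending row and locus.
* Rank-deficient designs (a contrast with no informative observations) are
  rejected before fitting, naming the offending columns via pivoted QR.
* LR statistics are clipped at zero; a negative value beyond −1e−3
  triggers a warning about ML convergence instead of silent clipping.
* Ensemble V_A/V_G ratios are the ratio of means and reported as NaN when
  the mean V_G is non-positive.
* The epistatic-deviation summary is computed over the four two-locus
  classes unobservable from single-segment lines (AABB, AaBB, AABb, AaBb)
  by default, with an all-nine-classes option. The synergism metric
  (Σ|non-epistatic| − Σ|epistatic|)/Σ|non-epistatic| is negative under
  synergism; because the denominator convention is not canonical, the
  alternative normalization by Σ|epistatic| is also reported.
* Pleiotropy correlations are Pearson correlations over all genetic-effect
  estimates (intercept excluded) with aligned labels across traits.

## Known limitations

* The crossed random-effect layout is slow for large datasets; the nested
  layout requires families not to span cohorts.
* Model-based covariances understate uncertainty if the residual model is
  misspecified (e.g. heteroscedastic traits); no sandwich estimator.
* Bias-corrected variances are unbiased but not variance-reduced; for very
  noisy effect estimates they can be negative, and consumers must be
  prepared for that.
* Only pairwise functional epistasis is modelled; three-way interactions
  and linkage disequilibrium are out of scope.
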