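# Methods

## Problem and model

Meta-analysing K GWAS that share individuals violates the independence
assumption behind both classical combination rules. Writing η̂_k for the
effect of a variant in study k (standard error σ_k) and
z_k = sign(η̂_k)·Φ⁻¹(1 − p_k/2) for its signed z-score, the package treats
the per-study statistics at one variant as a correlated Gaussian vector with
known marginal variances (Var z_k = 1 by construction, Var η̂_k = σ_k²) and
an inter-study correlation matrix R shared across variants. Covariances
follow the usual rule cov = r_kl·σ_k·σ_l, giving Ω_z (unit diagonal,
off-diagonal r_kl) for the p-value route and Ω_η (diagonal σ_k²) for the
effect-size route.

Estimators per variant:

| route | uncorrected | corrected |
|---|---|---|
| p-value | z = Σ√n_k z_k / √Σn_k | w_k = n_k/Σn, z = wᵀz/√(wᵀΩ_z w) |
| effect size | inverse variance, w_k ∝ 1/σ_k² | w = Ω_η⁻¹1/(1ᵀΩ_η⁻¹1), var = 1/(1ᵀΩ_η⁻¹1) |

Both corrected forms reduce to their classical counterparts when R = I
(verified to 1e-12 in tests). For variants missing from some studies the
correlation matrix is subset to the present studies and the weights
renormalize; no heterogeneity statistics are computed. Back-transformation
is p = 2(1 − Φ(|z|)), implemented via survival/inverse-survival functions so
p down to ~1e-300 round-trips to 10 significant digits; smaller p is not
representable and p = 0 input is rejected rather than clamped.

A genuine property of the generalized estimator worth knowing: for K = 2 the
corrected SE exceeds the naive one only while r ≤ 2σ₁σ₂/(σ₁²+σ₂²). Beyond
that bound (very unequal precisions under strong correlation) generalized
least squares legitimately outperforms naive pooling via a negative weight
on the noisier study. With equal SEs the bound is 1, so the familiar
"correction inflates the SE" intuition always holds for equally powered
studies.

## Estimating the inter-study correlation

* **Known overlap**: r = n₀/√(n₁n₂) for n₀ shared individuals.
* **Tetrachoric (default)**: each study's p-values over the shared variants
  are binarized at their own median — this makes the 2×2 cross-tabulation
  balanced ("equilibrated"), the regime in which the closed-form Digby
  approximation r ≈ (ω^{π/4}−1)/(ω^{π/4}+1), ω = ad/bc, is accurate. If any
  cell is zero, 0.5 is added to all four cells. The choice of the median as
  the cut (rather than a fixed p = 0.5) is a design decision: it guarantees
  balanced margins regardless of the p-value distribution, which a genomic
  signal or test miscalibration would otherwise skew.
* **Pearson**: product-moment correlation of signed z-scores.
* **ML cross-check**: an iterative tetrachoric MLE (margins fix the normal
  cut-points; the 2×2 multinomial likelihood is maximized over
  ρ ∈ (−0.999, 0.999) by bounded scalar minimization, tolerance 1e-6, with
  the bivariate normal CDF from scipy). It serves as the validation oracle
  for the Digby form: over 500 random balanced tables of total ≥ 1,000 the
  median |difference| is ~0.003 and the maximum ~0.015.

Estimated off-diagonals are capped at 0.99 in magnitude (configurable) so
that Ω stays invertible even for duplicated studies; negative estimates are
kept but warned about, since sample overlap alone cannot produce them.
Under the global null both estimators underestimate the true overlap
(dichotomization discards signal); under a polygenic burden both
overestimate it, the tetrachoric estimate less so because the median split
is insensitive to the tail inflation that drives Pearson's estimate up.

## Summary-statistic handling

Studies are matched on (chromosome, 1-based position, unordered allele
pair); the first study carrying a variant fixes the orientation and swapped
records are flipped (β → −β, EAF → 1 − EAF). Distinct allele sets at one
position remain distinct variants, so split multiallelics survive. Inputs
are assumed same-strand; palindromic A/T and C/G pairs are matched like any
others with a warning count, since strand flips cannot be detected from
summary data alone. Missing per-variant n falls back to the declared study
size. Rows violating basic invariants (SE ≤ 0, p ∉ (0,1], EAF ∉ [0,1]) are
rejected individually with a per-row reason.

## Simulation benchmark

The generator emulates the benchmark's study design: two cohorts of
**2,000** drawn from a common pool with the shared fraction swept over
0.5–75% of the per-study size; genotypes are Binomial(2, MAF) under HWE with
MAF ~ Uniform(0.05, 0.5); phenotypes are standard normal (null), carry one
causal SNP with allelic effect β = √(h2/(2·maf·(1−maf))) chosen so the SNP
explains **1%** of a unit-variance trait (power), or a polygenic burden
(for estimator accuracy: h² = 0.2 at 25% overlap). Association is
per-variant OLS — simulated individuals are unrelated, so a mixed model
would add nothing; the vectorized slope/SE/p agree with statsmodels OLS to
1e-9 in tests. The mega-analysis comparator pools individual-level data,
removes each duplicated individual once and absorbs study origin by
within-study centering (equivalent to a study-indicator covariate).

The false-positive rate is **per test** (share of null variant-tests below
α) with exact binomial CIs; power is the per-repeat detection rate of the
causal SNP. Desk-scale defaults — 5,000 null variants × 50 repeats at
α = 1e-3, 200 power repeats at α = 5e-8 — keep a full run in minutes while
leaving the binomial envelopes tight enough to separate corrected from
uncorrected behaviour; `SimConfig.paper_scale()` restores 1,000 repeats at
α = 5e-8. Overlap fractions are interpreted per study (75% of the combined
4,000 would exceed the largest possible overlap). Randomness flows from one
root seed through `SeedSequence.spawn`, so identical configurations
reproduce bitwise-identical results.

What the simulations do *not* emulate: linkage disequilibrium between
variants (each variant is drawn independently), relatedness beyond exact
duplication, allele-frequency spectra of real panels, imputation noise, or
case/control traits. Passing benchmarks therefore demonstrate the
estimators' behaviour under clean overlap, not performance on any
particular real cohort; with LD, the effective number of independent
p-values entering the tetrachoric table would shrink and its sampling noise
grow.

## Auxiliary statistics

* Fold enrichment E = (n_u/N_u)/(n_s/N_s) between cohort-unique and shared
  variant sets per MAF bin, with a pooled two-sample proportion z-test
  (two-sided, no continuity correction) and Bonferroni correction over the
  cells actually tested.
* MAF/MAC bins: MAC=2; MAC>2 & MAF≤1%; 1%<MAF≤2%; 2%<MAF≤5%; MAF>5%
  (right-closed); MAC<2 is excluded upstream.
* Effective number of independent phenotypes via the Li–Ji eigenvalue rule
  m_eff = Σ[I(λᵢ≥1) + (λᵢ−⌊λᵢ⌋)]; the adjusted genome-wide threshold is
  α/m_eff (5.00e-8 / 14.99 ≈ 3.34e-9).
* Imputation validation: per-allele concordance (correctly recovered allele
  copies over truth copies, majors and minors separately) and minor-allele
  PPV (correct minor calls over minor calls made); undefined denominators
  return None rather than a number.
* Replication: nominal two-sided p ≤ 0.05 in every dataset with a shared
  effect direction; an optional relaxed cut (e.g. 0.08) may be applied to a
  named small dataset.
* Prioritization: greedy selection of the smallest-p variant with
  p ≤ 5.00e-8, suppressing ±500 kbp on the same chromosome, ties broken by
  (chrom, pos); order-independent by construction.

## Numerical choices and limitations

Tetrachoric binarization uses ≤ median, so tied medians lean toward the
"significant" half; the all-equal vector maps to all ones. The ML estimator
clips cell probabilities at 1e-300 before taking logs. Correlation
estimation requires ≥ 100 shared variants per study pair (configurable) and
supports every-kth thinning; no LD pruning is applied by default since the
estimators are meant to consume all genome-wide statistics. The
variance-explained helper uses x/(1+x) with x = 2·eaf·(1−eaf)·β², the share
on a trait whose residual variance is 1 — a convention that matches
published per-variant numbers only to rounding, so it is reported, never
asserted exactly. Monomorphic variants are flagged and skipped, not
imputed. The benchmark at desk scale leaves ~±0.1 absolute noise in the
overlap-correlation accuracy medians; the tetrachoric-vs-Pearson ordering
is stable across seeds, the individual medians are not.
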