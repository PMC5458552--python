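# overlapmeta

Fixed-effects GWAS meta-analysis that accounts for **sample overlap between
studies**, using nothing but per-study summary statistics.

When two association studies share individuals (or relatives), their
per-variant statistics are positively correlated and a naive meta-analysis
double-counts evidence: false-positive rates inflate while the claimed
standard errors stay optimistically small. `overlapmeta` estimates the K×K
inter-study correlation matrix directly from genome-wide summary statistics
and folds it into the meta-analysis variance, so no individual-level data or
known overlap counts are required. It is aimed at statistical geneticists
meta-analysing cohorts genotyped in multiple tranches, within isolated or
founder populations, or across consortia with unknown sample sharing.

## The model

For K studies with per-variant effects η̂_k (SE σ_k), p-values p_k and
sample sizes n_k, both meta-statistics are weighted sums:

* signed z-scores z_k = sign(η̂_k)·Φ⁻¹(1 − p_k/2), combined as
  z_meta = wᵀz / √(wᵀ Ω_z w) with w_k = n_k/Σn, where Ω_z has unit
  diagonal and off-diagonal r_kl;
* effect sizes combined by generalized inverse variance,
  w = Ω_η⁻¹1 / (1ᵀΩ_η⁻¹1), var(η̂_meta) = 1/(1ᵀΩ_η⁻¹1), where
  Ω_η[k,l] = r_kl σ_k σ_l.

The inter-study correlation r_kl is either the expected value
n₀/√(n_k n_l) when the overlap count n₀ is known, or estimated from the
summary statistics themselves:

* **tetrachoric** — binarize each study's p-values at their median, cross-
  tabulate, and apply the Digby closed form (ω^{π/4}−1)/(ω^{π/4}+1) on the
  table's odds ratio ω = ad/bc (validated in-package against an iterative
  maximum-likelihood estimator); robust to a shared polygenic signal;
* **pearson** — product-moment correlation of the signed z-scores; more
  accurate under the global null, inflated by true shared signal.

With r ≡ 0 both corrected estimators reduce exactly to the classical
Stouffer and inverse-variance forms. The package also ships the simulation
benchmark that measures false-positive rate and power as a function of
overlap (including a genotype-level mega-analysis comparator), and the
auxiliary statistics of a cohort GWAS: fold enrichment with proportion
tests, effective-number-of-tests thresholds, imputation concordance/PPV,
replication flags and 500-kbp lead-variant prioritization.

## Worked example

```python
import overlapmeta as om

man = om.generate_fixture(n_per_study=2000, n_variants=500,
                          overlap_fraction=0.10, h2_snp=0.02,
                          seed=7, out_dir="fx")
studies = [om.read_summary(f, dialect="gemma", n_default=2000)
           for f in man["files"]]
panel = om.harmonize(studies)
corr = om.estimate_study_correlation(panel, method="tetrachoric")
results = om.meta_analyse(panel, corr)
print(results.sort_values("P_B_CORR").head(1)
      [["POS", "BETA_CORR", "SE_CORR", "P_B_CORR", "P_B_UNCORR"]])
```

prints (seed 7):

```
    POS  BETA_CORR  SE_CORR     P_B_CORR   P_B_UNCORR
2369781   0.245124 0.029201 4.687944e-17 7.725921e-18
```

The top hit is the planted causal variant (true allelic effect 0.266). Its
corrected p-value is about an order of magnitude *larger* than the
uncorrected one: the 200 shared samples contribute evidence once, not
twice — that gap is the overlap correction. More narrative walkthroughs
live in `examples/`.

The same pipeline is available from the shell:

```
overlapmeta corr fx/study1.sumstats.txt fx/study2.sumstats.txt \
    --n-default 2000 --out corr.tsv
overlapmeta meta fx/study1.sumstats.txt fx/study2.sumstats.txt \
    --n-default 2000 --correlation matrix:corr.tsv --out meta.tsv
```

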