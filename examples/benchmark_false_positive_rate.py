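"""Small-scale run of the overlap benchmark.

Simulates two cohorts of 1,000 over a grid of overlap fractions, tallies the
empirical false-positive rate of each meta-analysis flavour on null variants
at alpha = 1e-3, and the power on a single causal SNP. A few minutes of the
full-scale benchmark compressed into ~30 seconds.
"""

import overlapmeta as om

cfg = om.SimConfig(
    n_per_study=1000, n_variants=2000, overlap_grid=(0.0, 0.10, 0.25),
    n_repeats=10, alpha=1e-3, power_alpha=1e-6, seed=11,
    correlation_source="true",
)
res = om.run_benchmark(cfg)

wide = res.rates.pivot_table(index="overlap", columns="method", values="fpr")
print("empirical false-positive rate (nominal 1e-3):")
print((wide * 1e3).round(2).to_string())
print()
wide_p = res.rates.pivot_table(index="overlap", columns="method",
                               values="power")
print("power on a SNP explaining 1% of trait variance (alpha 1e-6):")
print(wide_p.round(2).to_string())

# Reading the FPR table (units of the nominal rate): the uncorrected columns
# drift above 1 as the overlap grows; the corrected columns and the
# deduplicated mega-analysis stay near 1. Power is similar across methods at
# low overlap and shrinks with the effective sample size.
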