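"""Simulation benchmark: false-positive rate and power under sample overlap.

Two GWAS cohorts of ``n_per_study`` individuals are drawn from a common pool
so that a controlled fraction of individuals appears in both. Genotypes are
simulated under Hardy-Weinberg equilibrium (dosage ~ Binomial(2, MAF), MAF
uniform over ``maf_range``); phenotypes are standard normal (null), carry a
single causal SNP explaining a fixed share of the variance (power), or a
polygenic burden spread over many SNPs (correlation-estimator accuracy).
Each study is associated by per-variant ordinary least squares — simulated
individuals are unrelated, so no mixed-model kinship term is needed — and
the studies are then combined by the four meta-analysis flavours plus a
genotype-level mega-analysis comparator (pooled regression with a study
covariate and duplicated individuals removed).

The tallies are the empirical false-positive rate (share of null variant
tests with p <= alpha) with exact binomial confidence intervals, the power
to detect the causal SNP, and the distribution of the tetrachoric and
Pearson estimates of the inter-study correlation against the known truth
n0/sqrt(n1*n2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import (
    binarize_pvalues,
    contingency_table,
    expected_correlation_from_overlap,
    pearson_z_correlation,
    tetrachoric_digby,
)
from .meta import p_to_z

logger = logging.getLogger(__name__)

META_METHODS = ["p_uncorrected", "p_corrected",
                "beta_uncorrected", "beta_corrected", "mega"]


@dataclass(frozen=True)
class NullTrait:
    """Phenotype independent of all genotypes (standard normal)."""


@dataclass(frozen=True)
class SingleSnpTrait:
    """One causal SNP explaining ``h2_snp`` of unit trait variance."""

    snp_index: int
    h2_snp: float


@dataclass(frozen=True)
class PolygenicTrait:
    """``m_causal`` standardized SNP effects with aggregate variance ``h2``."""

    m_causal: int
    h2: float


@dataclass
class SimConfig:
    """Benchmark configuration.

    Defaults follow the benchmark's study design — two cohorts of 2,000,
    overlap expressed as a fraction of the per-study size — at a desk scale
    (5,000 null variants, 50 repeats, alpha 1e-4) that keeps a full grid
    tractable on one CPU. ``paper_scale()`` restores the original scale of
    1,000 repeats at the genome-wide threshold 5e-8.
    """

    n_per_study: int = 2000
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    overlap_grid: tuple[float, ...] = (0.0, 0.005, 0.05, 0.10, 0.25, 0.50, 0.75)
    n_repeats: int = 50
    alpha: float = 1e-4
    seed: int = 0
    h2_snp: float = 0.01
    power_alpha: float = 5e-8
    power_repeats: int | None = None  # defaults to n_repeats
    correlation_source: str = "tetrachoric"  # tetrachoric | pearson | true
    polygenic: tuple[int, float] | None = None  # (m_causal, h2)

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if any(not 0 <= f <= 1 for f in self.overlap_grid):
            raise ValueError("overlap fractions must lie in [0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 <= self.h2_snp < 1):
            raise ValueError("h2_snp must lie in [0, 1)")
        if self.correlation_source not in {"tetrachoric", "pearson", "true"}:
            raise ValueError(f"unknown correlation_source "
                             f"{self.correlation_source!r}")

    @classmethod
    def paper_scale(cls, **overrides) -> "SimConfig":
        defaults = dict(
            n_variants=5000, n_repeats=1000, alpha=5e-8, power_alpha=5e-8,
            overlap_grid=(0.005, 0.01, 0.05, 0.10, 0.25, 0.50, 0.75),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SimResult:
    """Benchmark output: per-(overlap, method) rates and correlation estimates."""

    rates: pd.DataFrame       # overlap, method, fpr, fpr_lo, fpr_hi, power, ...
    correlations: pd.DataFrame  # overlap, repeat, tetrachoric, pearson, truth
    per_repeat: pd.DataFrame  # overlap, repeat, method, n_false_positive, n_tests
    config: SimConfig


def simulate_genotypes(
    n: int, m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """HWE genotype dosages: (n, m) int8 matrix and the true MAF vector."""
    if n < 1 or m < 1:
        raise ValueError("need n, m >= 1")
    rng = np.random.default_rng(rng)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m)
    g = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    return g, mafs


def draw_overlapping_studies(
    pool_size: int, n1: int, n2: int, n_overlap: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Index sets of two studies sharing exactly ``n_overlap`` individuals."""
    if n_overlap > min(n1, n2):
        raise ValueError("overlap exceeds a study size")
    if n1 + n2 - n_overlap > pool_size:
        raise ValueError("pool too small for requested sizes")
    rng = np.random.default_rng(rng)
    chosen = rng.choice(pool_size, size=n1 + n2 - n_overlap, replace=False)
    s1 = chosen[:n1]
    s2 = chosen[n1 - n_overlap:]
    return s1, s2


def effect_size_for_h2(maf: float, h2_snp: float) -> float:
    """Allelic effect giving additive variance ``h2_snp`` on a unit trait.

    beta = sqrt(h2 / (2 * maf * (1 - maf))).
    """
    if not (0 < maf < 1):
        raise ValueError("maf must lie strictly inside (0, 1)")
    if not (0 <= h2_snp < 1):
        raise ValueError("h2_snp must lie in [0, 1)")
    return float(np.sqrt(h2_snp / (2.0 * maf * (1.0 - maf))))


def simulate_phenotype(
    genotypes: np.ndarray,
    spec: NullTrait | SingleSnpTrait | PolygenicTrait,
    mafs: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Phenotype vector for the given genetic architecture (unit variance)."""
    rng = np.random.default_rng(rng)
    n, m = genotypes.shape
    if isinstance(spec, NullTrait):
        return rng.standard_normal(n)
    if isinstance(spec, SingleSnpTrait):
        if mafs is None:
            raise ValueError("single-SNP trait needs true MAFs")
        maf = float(mafs[spec.snp_index])
        beta = effect_size_for_h2(maf, spec.h2_snp)
        g = genotypes[:, spec.snp_index].astype(float)
        e = rng.standard_normal(n) * np.sqrt(1.0 - spec.h2_snp)
        return beta * (g - 2.0 * maf) + e
    if isinstance(spec, PolygenicTrait):
        if spec.m_causal > m:
            raise ValueError(f"requested {spec.m_causal} causal SNPs "
                             f"but only {m} are simulated")
        if mafs is None:
            raise ValueError("polygenic trait needs true MAFs")
        causal = rng.choice(m, size=spec.m_causal, replace=False)
        sd = np.sqrt(2.0 * mafs[causal] * (1.0 - mafs[causal]))
        u = (genotypes[:, causal] - 2.0 * mafs[causal]) / sd
        b = rng.standard_normal(spec.m_causal) * np.sqrt(spec.h2 / spec.m_causal)
        e = rng.standard_normal(n) * np.sqrt(1.0 - spec.h2)
        return u @ b + e
    raise TypeError(f"unknown phenotype spec {spec!r}")


def associate_ols(
    genotypes: np.ndarray, phenotype: np.ndarray
) -> pd.DataFrame:
    """Per-variant simple linear regression of phenotype on dosage.

    Vectorized over variants. Returns a DataFrame with columns beta, se, p,
    n; monomorphic variants get NaN statistics and ``skipped=True``.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n = g.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = yc @ gc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, 1e-300, 1.0)
    skipped = sxx <= 0
    beta[skipped] = np.nan
    out = pd.DataFrame({
        "BETA": beta, "SE": se, "P": p,
        "N": np.full(g.shape[1], n, dtype=float),
        "skipped": skipped,
    })
    return out


def associate_mega(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    study_labels: np.ndarray,
    dedup: bool = True,
    sample_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pooled regression with a study covariate, duplicates removed once.

    ``sample_ids`` identifies individuals across rows so that an individual
    present in both studies enters the regression once (its first row wins);
    without ids, rows are assumed unique. The study factor is projected out
    of dosage and phenotype (within-study centering) before the per-variant
    slope is estimated, which is equivalent to including study indicators.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    labels = np.asarray(study_labels)
    if len(labels) != g.shape[0]:
        raise ValueError("labels do not cover all samples")
    if dedup and sample_ids is not None:
        _, first = np.unique(np.asarray(sample_ids), return_index=True)
        keep = np.sort(first)
        g, y, labels = g[keep], y[keep], labels[keep]
    n = g.shape[0]
    groups = np.unique(labels)
    if n < len(groups) + 2:
        raise ValueError("too few distinct samples after deduplication")
    gc = g.copy()
    yc = y.copy()
    for lab in groups:
        mask = labels == lab
        gc[mask] -= gc[mask].mean(axis=0)
        yc[mask] -= yc[mask].mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = yc @ gc
    syy = float(yc @ yc)
    df = n - len(groups) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
        tstat = beta / se
    p = np.clip(2.0 * stats.t.sf(np.abs(tstat), df=df), 1e-300, 1.0)
    skipped = sxx <= 0
    beta[skipped] = np.nan
    return pd.DataFrame({
        "BETA": beta, "SE": se, "P": p,
        "N": np.full(g.shape[1], n, dtype=float), "skipped": skipped,
    })


def power_closed_form(n_total: float, h2_snp: float, alpha: float) -> float:
    """Normal-approximation power for one causal SNP in a sample of n_total.

    The association z-statistic is ~ N(ncp, 1) with noncentrality
    ncp = sqrt(n * h2 / (1 - h2)).
    """
    ncp = np.sqrt(n_total * h2_snp / (1.0 - h2_snp))
    zcrit = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.sf(zcrit - ncp) + stats.norm.cdf(-zcrit - ncp))


def _meta_two_studies(
    b1, s1, p1, b2, s2, p2, n1: float, n2: float, r: float
) -> dict[str, np.ndarray]:
    """Vectorized K=2 meta-analysis of per-variant statistics (all arrays)."""
    z1 = p_to_z(p1, np.where(b1 >= 0, 1.0, -1.0))
    z2 = p_to_z(p2, np.where(b2 >= 0, 1.0, -1.0))
    ntot = n1 + n2
    z_unc = (np.sqrt(n1) * z1 + np.sqrt(n2) * z2) / np.sqrt(ntot)
    w1, w2 = n1 / ntot, n2 / ntot
    denom = w1**2 + w2**2 + 2.0 * w1 * w2 * r
    z_cor = (w1 * z1 + w2 * z2) / np.sqrt(denom)
    # inverse-variance, uncorrected
    iv1, iv2 = 1.0 / s1**2, 1.0 / s2**2
    var_unc = 1.0 / (iv1 + iv2)
    b_unc = (iv1 * b1 + iv2 * b2) * var_unc
    se_unc = np.sqrt(var_unc)
    # generalized inverse-variance with off-diagonal r*s1*s2
    cov = r * s1 * s2
    det = (s1 * s2) ** 2 - cov**2
    sum_inv = (s1**2 + s2**2 - 2.0 * cov) / det  # 1' Omega^-1 1
    var_cor = 1.0 / sum_inv
    wa = (s2**2 - cov) / det * var_cor
    wb = (s1**2 - cov) / det * var_cor
    b_cor = wa * b1 + wb * b2
    se_cor = np.sqrt(var_cor)
    two = lambda z: np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return {
        "p_uncorrected": two(z_unc),
        "p_corrected": two(z_cor),
        "beta_uncorrected": two(b_unc / se_unc),
        "beta_corrected": two(b_cor / se_cor),
    }


def _estimate_pair_correlation(p1, p2, b1, b2) -> tuple[float, float]:
    """(tetrachoric, pearson) estimates from two studies' p and beta vectors."""
    t = contingency_table(binarize_pvalues(p1), binarize_pvalues(p2))
    r_tet = tetrachoric_digby(t)
    z1 = p_to_z(p1, np.where(b1 >= 0, 1.0, -1.0))
    z2 = p_to_z(p2, np.where(b2 >= 0, 1.0, -1.0))
    r_pear = pearson_z_correlation(z1, z2)
    return r_tet, r_pear


def _binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level,
                                             method="exact")
    return float(ci.low), float(ci.high)


def run_benchmark(config: SimConfig) -> SimResult:
    """Run the full overlap benchmark.

    Per overlap fraction and repeat: a null-phenotype scan of
    ``config.n_variants`` simulated variants tallies the false-positive
    rate of each method at ``config.alpha``; one single-SNP simulation
    (``h2_snp``) tallies power at ``config.power_alpha``; and the
    inter-study correlation is estimated by both routes. The corrected
    methods use the correlation named by ``config.correlation_source``.
    """
    cfg = config
    npr = cfg.n_per_study
    overlap_children = np.random.SeedSequence(cfg.seed).spawn(
        len(cfg.overlap_grid)
    )
    rate_rows = []
    corr_rows = []
    repeat_rows = []
    power_reps = cfg.power_repeats or cfg.n_repeats

    for oi, frac in enumerate(cfg.overlap_grid):
        n_overlap = int(round(frac * npr))
        pool = 2 * npr - n_overlap
        r_true = expected_correlation_from_overlap(n_overlap, npr, npr)
        fp = {m: 0 for m in META_METHODS}
        n_tests = 0
        det = {m: 0 for m in META_METHODS}

        children = overlap_children[oi].spawn(cfg.n_repeats + 1)
        for rep in range(cfg.n_repeats):
            rng = np.random.default_rng(children[rep])
            g, mafs = simulate_genotypes(pool, cfg.n_variants,
                                         cfg.maf_range, rng)
            y = simulate_phenotype(g, NullTrait(), mafs, rng)
            s1, s2 = draw_overlapping_studies(pool, npr, npr, n_overlap, rng)
            a1 = associate_ols(g[s1], y[s1])
            a2 = associate_ols(g[s2], y[s2])
            ok = ~(a1["skipped"] | a2["skipped"]).to_numpy()
            p1, p2 = a1["P"].to_numpy()[ok], a2["P"].to_numpy()[ok]
            b1, b2 = a1["BETA"].to_numpy()[ok], a2["BETA"].to_numpy()[ok]
            e1, e2 = a1["SE"].to_numpy()[ok], a2["SE"].to_numpy()[ok]

            r_tet, r_pear = _estimate_pair_correlation(p1, p2, b1, b2)
            corr_rows.append((frac, rep, r_tet, r_pear, r_true))
            r_used = {"tetrachoric": r_tet, "pearson": r_pear,
                      "true": r_true}[cfg.correlation_source]
            r_used = float(np.clip(r_used, -0.99, 0.99))

            pm = _meta_two_studies(b1, e1, p1, b2, e2, p2, npr, npr, r_used)
            labels = np.concatenate([np.zeros(npr), np.ones(npr)])
            ids = np.concatenate([s1, s2])
            mega = associate_mega(
                g[np.concatenate([s1, s2])], y[np.concatenate([s1, s2])],
                labels, dedup=True, sample_ids=ids,
            )
            pm["mega"] = mega["P"].to_numpy()[ok]
            n_tests += int(ok.sum())
            for m in META_METHODS:
                n_fp = int(np.sum(pm[m] <= cfg.alpha))
                fp[m] += n_fp
                repeat_rows.append((frac, rep, m, n_fp, int(ok.sum())))

        # power: single causal SNP per repeat, detection at power_alpha
        prng_children = children[cfg.n_repeats].spawn(power_reps)
        for rep in range(power_reps):
            rng = np.random.default_rng(prng_children[rep])
            g, mafs = simulate_genotypes(pool, 1, cfg.maf_range, rng)
            y = simulate_phenotype(g, SingleSnpTrait(0, cfg.h2_snp), mafs, rng)
            s1, s2 = draw_overlapping_studies(pool, npr, npr, n_overlap, rng)
            a1 = associate_ols(g[s1], y[s1])
            a2 = associate_ols(g[s2], y[s2])
            pm = _meta_two_studies(
                a1["BETA"].to_numpy(), a1["SE"].to_numpy(), a1["P"].to_numpy(),
                a2["BETA"].to_numpy(), a2["SE"].to_numpy(), a2["P"].to_numpy(),
                npr, npr, float(np.clip(r_true, 0, 0.99)),
            )
            labels = np.concatenate([np.zeros(npr), np.ones(npr)])
            ids = np.concatenate([s1, s2])
            mega = associate_mega(
                g[np.concatenate([s1, s2])], y[np.concatenate([s1, s2])],
                labels, dedup=True, sample_ids=ids,
            )
            pm["mega"] = mega["P"].to_numpy()
            for m in META_METHODS:
                det[m] += int(pm[m][0] <= cfg.power_alpha)

        for m in META_METHODS:
            flo, fhi = _binom_ci(fp[m], n_tests)
            plo, phi = _binom_ci(det[m], power_reps)
            rate_rows.append((
                frac, m, fp[m] / n_tests, flo, fhi, n_tests,
                det[m] / power_reps, plo, phi, power_reps,
            ))
        logger.info("overlap %.3f done", frac)

    rates = pd.DataFrame(rate_rows, columns=[
        "overlap", "method", "fpr", "fpr_lo", "fpr_hi", "n_tests",
        "power", "power_lo", "power_hi", "n_power_reps",
    ])
    corrs = pd.DataFrame(corr_rows, columns=[
        "overlap", "repeat", "tetrachoric", "pearson", "truth",
    ])
    per_repeat = pd.DataFrame(repeat_rows, columns=[
        "overlap", "repeat", "method", "n_false_positive", "n_tests",
    ])
    return SimResult(rates=rates, correlations=corrs, per_repeat=per_repeat,
                     config=cfg)


def plot_benchmark(result: SimResult, path: str) -> None:
    """Three-panel benchmark figure: FPR, power and correlation estimates
    against the overlap fraction. Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for m in META_METHODS:
        sub = result.rates[result.rates["method"] == m]
        axes[0].plot(sub["overlap"], sub["fpr"], marker="o", label=m)
        axes[1].plot(sub["overlap"], sub["power"], marker="o", label=m)
    axes[0].axhline(result.config.alpha, ls="--", c="k", lw=0.8)
    axes[0].set(xlabel="overlap fraction", ylabel="false-positive rate")
    axes[1].set(xlabel="overlap fraction", ylabel="power")
    axes[0].legend(fontsize=7)
    med = result.correlations.groupby("overlap").median()
    axes[2].plot(med.index, med["tetrachoric"], marker="o",
                 label="tetrachoric")
    axes[2].plot(med.index, med["pearson"], marker="s", label="pearson")
    axes[2].plot(med.index, med["truth"], ls="--", c="k", label="truth")
    axes[2].set(xlabel="overlap fraction", ylabel="estimated correlation")
    axes[2].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def evaluate_correlation_estimators(
    config: SimConfig, overlap: float = 0.25
) -> pd.DataFrame:
    """Accuracy of the tetrachoric vs Pearson overlap estimators.

    Requires ``config.polygenic``; each replicate simulates a polygenic
    burden over the panel (truly associated, correlated statistics in both
    studies), associates each study and records both estimates beside the
    true overlap correlation. Returns per-replicate rows; medians and
    interquintile ranges are a one-line groupby away.
    """
    if config.polygenic is None:
        raise ValueError("config.polygenic=(m_causal, h2) is required")
    m_causal, h2 = config.polygenic
    npr = config.n_per_study
    n_overlap = int(round(overlap * npr))
    pool = 2 * npr - n_overlap
    r_true = expected_correlation_from_overlap(n_overlap, npr, npr)
    rows = []
    children = np.random.SeedSequence(config.seed).spawn(config.n_repeats)
    for rep in range(config.n_repeats):
        rng = np.random.default_rng(children[rep])
        g, mafs = simulate_genotypes(pool, config.n_variants,
                                     config.maf_range, rng)
        spec = (NullTrait() if h2 == 0
                else PolygenicTrait(m_causal=m_causal, h2=h2))
        y = simulate_phenotype(g, spec, mafs, rng)
        s1, s2 = draw_overlapping_studies(pool, npr, npr, n_overlap, rng)
        a1 = associate_ols(g[s1], y[s1])
        a2 = associate_ols(g[s2], y[s2])
        ok = ~(a1["skipped"] | a2["skipped"]).to_numpy()
        r_tet, r_pear = _estimate_pair_correlation(
            a1["P"].to_numpy()[ok], a2["P"].to_numpy()[ok],
            a1["BETA"].to_numpy()[ok], a2["BETA"].to_numpy()[ok],
        )
        rows.append((rep, r_tet, r_pear, r_true))
    return pd.DataFrame(rows, columns=["repeat", "tetrachoric", "pearson",
                                       "truth"])
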