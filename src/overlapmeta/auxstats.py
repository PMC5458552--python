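"""Auxiliary statistics around a GWAS: enrichment, thresholds, validation.

Covers the descriptive and decision statistics that accompany a cohort
association study: fold enrichment of functional consequence classes between
a cohort-unique and a shared variant set (with a two-sided proportion test
and Bonferroni correction), MAF/MAC binning, the effective number of
independent phenotypes and the resulting adjusted genome-wide threshold,
per-allele concordance and positive predictive value of imputed genotypes
against direct genotyping, replication flags, and window-based prioritization
of lead variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MAF_BINS = ["MAC=2", "MAC>2 & MAF<=1%", "1%<MAF<=2%", "2%<MAF<=5%", "MAF>5%"]

GENOME_WIDE_ALPHA = 5.00e-8


@dataclass(frozen=True)
class EnrichmentCell:
    """Counts of one consequence class within one MAF bin, unique vs shared.

    ``n_unique``/``n_shared`` variants of consequence ``consequence`` out of
    ``total_unique``/``total_shared`` variants in MAF bin ``maf_bin``.
    """

    maf_bin: str
    consequence: str
    n_unique: int
    total_unique: int
    n_shared: int
    total_shared: int

    def __post_init__(self) -> None:
        if self.total_unique < 1 or self.total_shared < 1:
            raise ValueError("bin totals must be >= 1")
        if not (0 <= self.n_unique <= self.total_unique):
            raise ValueError("n_unique outside [0, total_unique]")
        if not (0 <= self.n_shared <= self.total_shared):
            raise ValueError("n_shared outside [0, total_shared]")

    def swapped(self) -> "EnrichmentCell":
        return EnrichmentCell(self.maf_bin, self.consequence,
                              self.n_shared, self.total_shared,
                              self.n_unique, self.total_unique)


def assign_maf_bin(mac: int, maf: float) -> str:
    """Frequency bin of a variant (right-closed boundaries).

    Singletons and monomorphics (MAC < 2) are filtered upstream and rejected
    here.
    """
    if mac < 2:
        raise ValueError("filtered class: MAC < 2 is excluded upstream")
    if not (0 < maf <= 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    if mac == 2:
        return "MAC=2"
    if maf <= 0.01:
        return "MAC>2 & MAF<=1%"
    if maf <= 0.02:
        return "1%<MAF<=2%"
    if maf <= 0.05:
        return "2%<MAF<=5%"
    return "MAF>5%"


def fold_enrichment(cell: EnrichmentCell) -> float:
    """Ratio of within-bin consequence proportions, unique over shared.

    E = (n_u / N_u) / (n_s / N_s). With no shared variants of the class the
    ratio is unbounded and ``inf`` is returned (an "infinite enrichment"
    flag value, not a usable number).
    """
    pu = cell.n_unique / cell.total_unique
    ps = cell.n_shared / cell.total_shared
    if ps == 0:
        return math.inf
    return pu / ps


def proportion_test(cell: EnrichmentCell) -> float:
    """Two-sided pooled-variance z-test for equality of the two proportions."""
    x1, n1 = cell.n_unique, cell.total_unique
    x2, n2 = cell.n_shared, cell.total_shared
    if x1 == 0 and x2 == 0:
        return 1.0
    pool = (x1 + x2) / (n1 + n2)
    denom = math.sqrt(pool * (1.0 - pool) * (1.0 / n1 + 1.0 / n2))
    if denom == 0:
        return 1.0
    z = (x1 / n1 - x2 / n2) / denom
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def bonferroni(p, m: int | None = None):
    """Bonferroni-adjusted p-values: min(1, m*p); m defaults to len(p)."""
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(~((p_arr > 0) & (p_arr <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    mm = len(p_arr) if m is None else int(m)
    if mm < 1:
        raise ValueError("m must be >= 1")
    adj = np.minimum(1.0, mm * p_arr)
    return float(adj[0]) if np.isscalar(p) else adj


def enrichment_table(cells: list[EnrichmentCell]) -> pd.DataFrame:
    """Fold enrichment, proportion-test p and Bonferroni-adjusted p per cell.

    The Bonferroni multiplicity is the number of cells actually tested.
    """
    rows = [(c.maf_bin, c.consequence, fold_enrichment(c), proportion_test(c))
            for c in cells]
    df = pd.DataFrame(rows, columns=["maf_bin", "consequence",
                                     "fold_enrichment", "p"])
    df["p_bonferroni"] = bonferroni(df["p"].to_numpy(), m=len(df))
    return df


def effective_n_tests(trait_corr: np.ndarray) -> float:
    """Effective number of independent tests from a trait correlation matrix.

    Eigenvalue-based (Li & Ji 2005): m_eff = sum over eigenvalues of
    I(lambda >= 1) + (lambda - floor(lambda)), which equals the matrix
    dimension for an identity matrix and 1 for a rank-one all-ones matrix.
    """
    m = np.asarray(trait_corr, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(m)
    if lam.min() < -1e-8:
        raise ValueError("correlation matrix has negative eigenvalues")
    lam = np.abs(lam)
    m_eff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    # the estimator is bounded by [1, dim]; trim floating-point spill
    return float(np.clip(m_eff, 1.0, m.shape[0]))


def adjusted_threshold(alpha: float, m_eff: float) -> float:
    """Genome-wide threshold controlling FWER over m_eff independent tests."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m_eff


def concordance_ppv(
    validated: np.ndarray, imputed: np.ndarray
) -> tuple[float | None, float | None, float | None]:
    """Per-allele concordance and PPV of imputed vs directly typed genotypes.

    Genotypes are minor-allele dosages in {0, 1, 2}; negative values mark
    missing calls and are excluded pairwise. Denominators are allele copies:
    concordance of an allele is the number of correctly recovered copies over
    the number of truth copies; PPV of the minor allele is correctly called
    minor copies over all minor copies called. Undefined ratios (zero truth
    copies / zero calls) return None.
    """
    t = np.asarray(validated, dtype=float)
    i = np.asarray(imputed, dtype=float)
    if t.shape != i.shape:
        raise ValueError("call vectors differ in length")
    ok = (t >= 0) & (i >= 0)
    t, i = t[ok], i[ok]
    minor_truth = float(t.sum())
    major_truth = float((2 - t).sum())
    minor_called = float(i.sum())
    correct_minor = float(np.minimum(t, i).sum())
    correct_major = float(np.minimum(2 - t, 2 - i).sum())
    conc_major = correct_major / major_truth if major_truth > 0 else None
    conc_minor = correct_minor / minor_truth if minor_truth > 0 else None
    ppv_minor = correct_minor / minor_called if minor_called > 0 else None
    return conc_major, conc_minor, ppv_minor


def replication_flag(
    results: list[tuple[float, float]],
    p_cut: float = 0.05,
    relaxed_cut: float | None = None,
    relaxed_index: int | None = None,
) -> bool:
    """Replication rule across datasets: nominal p and consistent direction.

    ``results`` holds per-dataset (beta, p) pairs. True iff every dataset
    reaches its threshold (``relaxed_cut`` replaces ``p_cut`` for the dataset
    at ``relaxed_index``, or for all datasets when no index is given) and all
    betas share one sign. A zero beta has no direction and fails the rule.
    """
    if len(results) < 2:
        raise ValueError("need results from at least 2 datasets")
    signs = set()
    for idx, (beta, p) in enumerate(results):
        cut = p_cut
        if relaxed_cut is not None and (relaxed_index is None
                                        or idx == relaxed_index):
            cut = relaxed_cut
        if not (0 < p <= 1) or p > cut:
            return False
        if beta == 0:
            return False
        signs.add(beta > 0)
    return len(signs) == 1


def prioritize_signals(
    results: pd.DataFrame,
    window: int = 500_000,
    threshold: float = GENOME_WIDE_ALPHA,
    p_column: str = "P",
) -> pd.DataFrame:
    """Greedy window-based selection of lead variants.

    Repeatedly takes the smallest-p variant with p <= threshold and
    suppresses every variant within ±window bp on the same chromosome; ties
    on p are broken by (chromosome, position). The outcome is independent of
    input row order, and selected leads are pairwise more than ``window``
    apart per chromosome.
    """
    req = {"CHROM", "POS", p_column}
    missing = req - set(results.columns)
    if missing:
        raise ValueError(f"results lack column(s) {sorted(missing)}")
    sig = results[results[p_column] <= threshold]
    sig = sig.sort_values([p_column, "CHROM", "POS"],
                          kind="mergesort").reset_index(drop=True)
    leads = []
    suppressed = np.zeros(len(sig), dtype=bool)
    chroms = sig["CHROM"].to_numpy()
    poss = sig["POS"].to_numpy()
    for i in range(len(sig)):
        if suppressed[i]:
            continue
        leads.append(i)
        hit = (chroms == chroms[i]) & (np.abs(poss - poss[i]) <= window)
        suppressed |= hit
    out = sig.iloc[leads].reset_index(drop=True)
    return out
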