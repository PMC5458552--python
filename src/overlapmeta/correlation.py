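"""Estimating the K×K inter-study correlation from summary statistics.

Shared or related individuals between two GWAS induce a correlation between
the studies' test statistics at every variant. When the number of overlapping
individuals n0 is known, that correlation is simply n0/sqrt(n1*n2). When it
is not, it can be estimated from the genome-wide statistics themselves:

* **Tetrachoric route** — binarize each study's p-values at their median
  (producing a balanced, "equilibrated" 2x2 table when cross-tabulated
  against a second study), then estimate the latent bivariate-normal
  correlation from the table. The closed-form Digby approximation
  (omega^(pi/4) - 1)/(omega^(pi/4) + 1), with omega = ad/bc the table's odds
  ratio, is accurate for balanced tables of large total count; an iterative
  maximum-likelihood estimator is provided as a cross-check.
* **Pearson route** — product-moment correlation of the signed per-variant
  z-scores. Simpler, but sensitive to a shared polygenic signal, which
  inflates it; the tetrachoric route is robust to such outliers.

The estimated matrix feeds two covariance matrices: Omega_z for the p-value
meta-analysis (unit diagonal, off-diagonal r_kl) and Omega_eta for the
effect-size meta-analysis (diagonal SE_k^2, off-diagonal r_kl*SE_k*SE_l).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .sumstats import AlignedPanel

logger = logging.getLogger(__name__)

#: default cap on |off-diagonal| correlation, keeps Omega invertible
DEFAULT_CAP = 0.99


@dataclass(frozen=True)
class Table2x2:
    """Counts from cross-tabulating two binary vectors.

    a: both 1, b: first only, c: second only, d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total < 1:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> tuple[float, float, float, float]:
        """Cells with +0.5 added to every cell if any cell is zero."""
        cells = (self.a, self.b, self.c, self.d)
        if min(cells) == 0:
            return tuple(x + 0.5 for x in cells)  # type: ignore[return-value]
        return tuple(float(x) for x in cells)  # type: ignore[return-value]


@dataclass
class StudyCorrelation:
    """Symmetric K×K correlation matrix between studies' statistics."""

    matrix: np.ndarray
    method: str
    study_ids: list[str]
    n_variants_used: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        self.matrix = m

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CovarianceMatrices:
    """Omega_z (p-value route) and Omega_eta (effect-size route)."""

    omega_z: np.ndarray
    omega_eta: np.ndarray


def binarize_pvalues(p: np.ndarray) -> np.ndarray:
    """Indicator of p <= median(p), as 0/1 integers.

    The median split balances the margin to within one count, which is the
    regime in which the Digby closed form approximates the tetrachoric
    correlation well.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 p-values to binarize")
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    return (p <= np.median(p)).astype(np.int8)


def contingency_table(bx: np.ndarray, by: np.ndarray) -> Table2x2:
    """Cross-tabulate two equal-length binary vectors."""
    bx = np.asarray(bx)
    by = np.asarray(by)
    if bx.shape != by.shape:
        raise ValueError(f"length mismatch: {bx.shape} vs {by.shape}")
    a = int(np.sum((bx == 1) & (by == 1)))
    b = int(np.sum((bx == 1) & (by == 0)))
    c = int(np.sum((bx == 0) & (by == 1)))
    d = int(np.sum((bx == 0) & (by == 0)))
    return Table2x2(a, b, c, d)


def tetrachoric_digby(t: Table2x2) -> float:
    """Closed-form tetrachoric correlation from the table's odds ratio.

    Returns (omega^(pi/4) - 1)/(omega^(pi/4) + 1) with omega = ad/bc, after
    adding 0.5 to every cell if any cell is zero.
    """
    a, b, c, d = t.corrected()
    omega = (a * d) / (b * c)
    w = omega ** (np.pi / 4.0)
    return float((w - 1.0) / (w + 1.0))


def _table_loglik(rho: float, t: tuple[float, float, float, float],
                  hx: float, hy: float) -> float:
    """Multinomial log-likelihood of the 2x2 table under a latent bivariate
    normal with correlation rho and dichotomization thresholds hx, hy."""
    a, b, c, d = t
    # P(X <= hx, Y <= hy) under the bivariate normal
    bvn = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    )
    p11 = bvn.cdf([hx, hy])
    px = stats.norm.cdf(hx)
    py = stats.norm.cdf(hy)
    p10 = px - p11
    p01 = py - p11
    p00 = 1.0 - px - py + p11
    probs = np.clip([p11, p10, p01, p00], 1e-300, 1.0)
    return float(np.dot([a, b, c, d], np.log(probs)))


def tetrachoric_ml(t: Table2x2, tol: float = 1e-6) -> float:
    """Maximum-likelihood tetrachoric correlation.

    Thresholds are fixed at the normal quantiles of the observed margins and
    the 2x2 multinomial likelihood is maximized over rho in (-0.999, 0.999)
    by bounded scalar minimization. Serves as the validation oracle for the
    Digby closed form.
    """
    a, b, c, d = t.corrected()
    n = a + b + c + d
    # margins: "1" means below-threshold (p <= median), so threshold is the
    # quantile of the row/column proportion of ones
    hx = stats.norm.ppf((a + b) / n)
    hy = stats.norm.ppf((a + c) / n)
    if not (np.isfinite(hx) and np.isfinite(hy)):
        raise ValueError("degenerate margin after continuity correction")

    res = optimize.minimize_scalar(
        lambda r: -_table_loglik(r, (a, b, c, d), hx, hy),
        bounds=(-0.999, 0.999),
        method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise RuntimeError(
            f"tetrachoric ML did not converge (last iterate {res.x:.6f})"
        )
    return float(res.x)


def pearson_z_correlation(z1: np.ndarray, z2: np.ndarray) -> float:
    """Pearson product-moment correlation of two z-score vectors."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape or z1.size < 3:
        raise ValueError("need equal-length vectors of at least 3 z-scores")
    if not (np.all(np.isfinite(z1)) and np.all(np.isfinite(z2))):
        raise ValueError("non-finite z-scores")
    if np.std(z1) == 0 or np.std(z2) == 0:
        raise ValueError("zero variance in z-scores")
    return float(np.corrcoef(z1, z2)[0, 1])


def expected_correlation_from_overlap(n0: float, n1: float, n2: float) -> float:
    """Correlation implied by a known count of shared individuals: n0/sqrt(n1*n2)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("study sizes must be >= 1")
    if not (0 <= n0 <= min(n1, n2)):
        raise ValueError(f"overlap {n0} outside [0, min(n1, n2)]")
    return float(n0 / np.sqrt(n1 * n2))


def _signed_z(beta: np.ndarray, p: np.ndarray) -> np.ndarray:
    from .meta import p_to_z

    return p_to_z(p, np.where(beta >= 0, 1.0, -1.0))


def estimate_study_correlation(
    panel: AlignedPanel,
    method: str = "tetrachoric",
    cap: float = DEFAULT_CAP,
    min_shared: int = 100,
    thin: int = 1,
) -> StudyCorrelation:
    """Estimate the inter-study correlation matrix from an aligned panel.

    For each study pair the variants present in both are collected (optionally
    thinned to every ``thin``-th variant); the pairwise correlation is then
    the Digby tetrachoric estimate on the median-binarized p-values, or the
    Pearson correlation of signed z-scores. Off-diagonal magnitudes are
    capped at ``cap``; negative estimates are retained with a warning, since
    sample overlap alone cannot produce them.
    """
    if method not in {"tetrachoric", "pearson"}:
        raise ValueError(f"unknown method {method!r}")
    if not (0 < cap < 1):
        raise ValueError("cap must lie in (0, 1)")
    k = panel.k
    mat = np.eye(k)
    pcols = [panel.variants[c].to_numpy(dtype=float)
             for c in panel.study_columns("P")]
    bcols = [panel.variants[c].to_numpy(dtype=float)
             for c in panel.study_columns("BETA")]
    n_used = 0
    for i in range(k):
        for j in range(i + 1, k):
            shared = np.isfinite(pcols[i]) & np.isfinite(pcols[j])
            idx = np.flatnonzero(shared)[::max(1, int(thin))]
            if idx.size < min_shared:
                raise ValueError(
                    f"studies {panel.studies[i]!r} and {panel.studies[j]!r} "
                    f"share only {idx.size} variants (< {min_shared})"
                )
            n_used = max(n_used, idx.size)
            if method == "tetrachoric":
                bi = binarize_pvalues(pcols[i][idx])
                bj = binarize_pvalues(pcols[j][idx])
                r = tetrachoric_digby(contingency_table(bi, bj))
            else:
                zi = _signed_z(bcols[i][idx], pcols[i][idx])
                zj = _signed_z(bcols[j][idx], pcols[j][idx])
                r = pearson_z_correlation(zi, zj)
            if r < 0:
                logger.warning(
                    "negative inter-study correlation %.4f for (%s, %s); "
                    "sample overlap implies r >= 0 — retained as estimated",
                    r, panel.studies[i], panel.studies[j],
                )
            r = float(np.clip(r, -cap, cap))
            mat[i, j] = mat[j, i] = r
    return StudyCorrelation(
        matrix=mat, method=method, study_ids=list(panel.studies),
        n_variants_used=n_used,
    )


def build_covariance_matrices(
    corr: StudyCorrelation | np.ndarray, se: np.ndarray
) -> CovarianceMatrices:
    """Build Omega_z and Omega_eta for one variant.

    Omega_z has unit diagonal (each z_k has unit variance by construction)
    and off-diagonal r_kl; Omega_eta has diagonal SE_k^2 and off-diagonal
    r_kl * SE_k * SE_l (the usual covariance-from-correlation rule, with the
    per-study variances known from the input files).
    """
    r = corr.matrix if isinstance(corr, StudyCorrelation) else np.asarray(corr)
    se = np.asarray(se, dtype=float)
    if np.any(~(se > 0)):
        raise ValueError("standard errors must be strictly positive")
    if r.shape != (se.size, se.size):
        raise ValueError("correlation/SE dimension mismatch")
    omega_z = r.copy()
    omega_eta = r * np.outer(se, se)
    return CovarianceMatrices(omega_z=omega_z, omega_eta=omega_eta)


def read_correlation_matrix(path) -> StudyCorrelation:
    """Read a plain-text correlation matrix with a study-id header row."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return StudyCorrelation(
        matrix=df.to_numpy(dtype=float),
        method="user",
        study_ids=[str(c) for c in df.columns],
    )


def write_correlation_matrix(corr: StudyCorrelation, path) -> None:
    import pandas as pd

    pd.DataFrame(
        corr.matrix, index=corr.study_ids, columns=corr.study_ids
    ).to_csv(path, sep="\t", float_format="%.10g")
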