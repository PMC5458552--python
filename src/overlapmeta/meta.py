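"""Per-variant fixed-effects meta-analysis with overlap-aware variances.

Four estimators are computed per variant, all weighted sums of the per-study
statistics:

* uncorrected p-value route (Stouffer): z = sum(sqrt(n_k) z_k) / sqrt(sum n_k)
* corrected p-value route: w_k = n_k / sum(n), z = w'z / sqrt(w' Omega_z w)
* uncorrected effect-size route: classical inverse-variance fixed effects
* corrected effect-size route: w = Omega_eta^-1 1 / (1' Omega_eta^-1 1),
  beta = w' beta, var = 1 / (1' Omega_eta^-1 1)

where z_k = sign(beta_k) * Phi^-1(1 - p_k / 2) is the signed z-score of the
two-sided p-value and Omega_z / Omega_eta are the covariance matrices built
from the estimated inter-study correlation. With a diagonal Omega (no
overlap) the corrected effect-size route reduces exactly to the classical
inverse-variance estimator; with positive inter-study correlation its
standard error is inflated, removing the spurious precision a naive
meta-analysis would claim from double-counted individuals.

p-values are handled in survival-function space so that inputs down to about
1e-300 survive the round trip without underflow.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import StudyCorrelation, build_covariance_matrices
from .sumstats import META_COLUMNS, AlignedPanel

logger = logging.getLogger(__name__)

_MIN_P = 1e-300


def p_to_z(p, sign):
    """Signed z-score of a two-sided p-value: sign * Phi^-1(1 - p/2).

    Computed via the inverse survival function, so p as small as ~1e-300 is
    representable. Accepts scalars or arrays.
    """
    p_arr = np.asarray(p, dtype=float)
    s = np.asarray(sign, dtype=float)
    if np.any(~((p_arr > 0) & (p_arr <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(np.abs(s) != 1):
        raise ValueError("sign must be +1 or -1")
    z = s * stats.norm.isf(p_arr / 2.0)
    return float(z) if np.isscalar(p) or p_arr.ndim == 0 else z


def z_to_p(z):
    """Two-sided p-value of a z-score: 2 * (1 - Phi(|z|)), floor 1e-300."""
    z_arr = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z_arr)):
        raise ValueError("non-finite z-score")
    p = 2.0 * stats.norm.sf(np.abs(z_arr))
    p = np.maximum(p, _MIN_P)
    return float(p) if np.isscalar(z) or z_arr.ndim == 0 else p


def _check_omega(omega: np.ndarray, k: int, unit_diag: bool) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (k, k):
        raise ValueError(f"covariance matrix must be {k}x{k}")
    if not np.allclose(omega, omega.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    if unit_diag and not np.allclose(np.diag(omega), 1.0, atol=1e-10):
        raise ValueError("Omega_z must have unit diagonal")
    return omega


def meta_p_uncorrected(z: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Sample-size-weighted Stouffer combination ignoring overlap.

    z_meta = sum(sqrt(n_k) z_k) / sqrt(sum n_k).
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if z.shape != n.shape:
        raise ValueError("z and n length mismatch")
    z_meta = float(np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n)))
    return z_meta, z_to_p(z_meta)


def meta_p_corrected(
    z: np.ndarray, n: np.ndarray, omega_z: np.ndarray
) -> tuple[float, float]:
    """Relative-sample-size-weighted z combination with overlap-aware variance.

    w_k = n_k / sum(n); z_meta = w'z / sqrt(w' Omega_z w).
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    omega_z = _check_omega(omega_z, z.size, unit_diag=True)
    w = n / np.sum(n)
    denom = float(w @ omega_z @ w)
    if denom <= 0:
        raise ValueError("Omega_z is not positive definite for these weights")
    z_meta = float(w @ z / np.sqrt(denom))
    return z_meta, z_to_p(z_meta)


def meta_beta_uncorrected(
    beta: np.ndarray, se: np.ndarray
) -> tuple[float, float, float]:
    """Classical fixed-effects inverse-variance meta-analysis."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(~(se > 0)):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    var = 1.0 / np.sum(w)
    b = float(np.sum(w * beta) * var)
    s = float(np.sqrt(var))
    return b, s, z_to_p(b / s)


def meta_beta_corrected(
    beta: np.ndarray, omega_eta: np.ndarray
) -> tuple[float, float, float]:
    """Generalized inverse-variance meta-analysis under a full covariance.

    w = Omega^-1 1 / (1' Omega^-1 1); var(beta_meta) = 1 / (1' Omega^-1 1).
    Reduces to the classical estimator when Omega is diagonal.
    """
    beta = np.asarray(beta, dtype=float)
    k = beta.size
    omega = _check_omega(omega_eta, k, unit_diag=False)
    ones = np.ones(k)
    try:
        oinv_1 = np.linalg.solve(omega, ones)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "Omega_eta is singular; lower the correlation cap"
        ) from exc
    denom = float(ones @ oinv_1)
    if denom <= 0:
        raise ValueError("Omega_eta is not positive definite")
    w = oinv_1 / denom
    b = float(w @ beta)
    s = float(np.sqrt(1.0 / denom))
    return b, s, z_to_p(b / s)


def variance_explained(beta: float, eaf: float) -> float:
    """Share of phenotypic variance explained by one variant.

    With x = 2*eaf*(1-eaf)*beta^2 the additive variance contributed on a
    trait whose residual variance is 1, returns x / (1 + x).
    """
    if not (0 < eaf < 1):
        raise ValueError("eaf must lie strictly inside (0, 1)")
    x = 2.0 * eaf * (1.0 - eaf) * float(beta) ** 2
    return x / (1.0 + x)


def meta_analyse(
    panel: AlignedPanel,
    corr: StudyCorrelation | np.ndarray,
    min_studies: int = 1,
) -> pd.DataFrame:
    """Run all four meta-analysis flavours over an aligned panel.

    For each variant carried by at least ``min_studies`` studies, the
    correlation matrix is subset to the present studies, Omega_z / Omega_eta
    are built from it and the per-study SEs, and the four estimators are
    computed. Variants with fewer studies are skipped and counted; a
    per-variant numerical failure aborts that variant only.

    Returns a DataFrame with columns :data:`overlapmeta.sumstats.META_COLUMNS`.
    """
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    r_full = corr.matrix if isinstance(corr, StudyCorrelation) else np.asarray(corr)
    k = panel.k
    if r_full.shape != (k, k):
        raise ValueError("correlation dimension does not match panel")

    v = panel.variants
    beta_m = v[panel.study_columns("BETA")].to_numpy(dtype=float)
    se_m = v[panel.study_columns("SE")].to_numpy(dtype=float)
    p_m = v[panel.study_columns("P")].to_numpy(dtype=float)
    n_m = v[panel.study_columns("N")].to_numpy(dtype=float)
    present = np.isfinite(beta_m) & np.isfinite(se_m) & np.isfinite(p_m)
    z_m = np.full_like(beta_m, np.nan)
    ok = present
    z_m[ok] = p_to_z(p_m[ok], np.where(beta_m[ok] >= 0, 1.0, -1.0))

    rows = []
    n_skipped = 0
    n_failed = 0
    for i in range(len(v)):
        idx = np.flatnonzero(present[i])
        if idx.size < min_studies:
            n_skipped += 1
            continue
        sub_r = r_full[np.ix_(idx, idx)]
        b, s, p, n, z = (beta_m[i, idx], se_m[i, idx], p_m[i, idx],
                         n_m[i, idx], z_m[i, idx])
        try:
            cov = build_covariance_matrices(sub_r, s)
            zu, pzu = meta_p_uncorrected(z, n)
            zc, pzc = meta_p_corrected(z, n, cov.omega_z)
            bu, su, pbu = meta_beta_uncorrected(b, s)
            bc, sc, pbc = meta_beta_corrected(b, cov.omega_eta)
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.warning("variant %s:%s failed: %s",
                           v["CHROM"].iat[i], v["POS"].iat[i], exc)
            continue
        rows.append((
            v["CHROM"].iat[i], v["POS"].iat[i], v["EA"].iat[i], v["NEA"].iat[i],
            idx.size, float(np.sum(n)),
            zu, pzu, zc, pzc, bu, su, pbu, bc, sc, pbc,
        ))
    if n_skipped:
        logger.info("skipped %d variant(s) with < %d studies",
                    n_skipped, min_studies)
    if n_failed:
        logger.warning("%d variant(s) failed numerically", n_failed)
    out = pd.DataFrame(rows, columns=META_COLUMNS)
    return out
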