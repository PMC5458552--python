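"""Synthetic paired-study fixtures and pipeline orchestration.

``generate_fixture`` runs the simulation pipeline end to end — simulate HWE
genotypes for a pool, draw two overlapping cohorts, simulate a phenotype,
associate each cohort by OLS — and writes the two resulting summary-statistic
files in the GEMMA column dialect, together with a JSON manifest recording
the ground truth (overlap correlation n0/sqrt(n1*n2), causal variant, true
effect size). Half of the second study's rows are written in the swapped
allele orientation so that downstream harmonization is exercised.

``run_pipeline`` chains read -> harmonize -> correlate -> meta-analyse ->
write for any number of studies.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import correlation as corrmod
from . import meta as metamod
from . import simulate as simmod
from . import sumstats

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


def _variant_frame(m: int, rng: np.random.Generator) -> pd.DataFrame:
    """Random biallelic variant annotations on chromosome 1."""
    pos = np.sort(rng.choice(np.arange(1, 25_000_000), size=m, replace=False))
    a1 = rng.integers(0, 4, size=m)
    a2 = (a1 + rng.integers(1, 4, size=m)) % 4
    return pd.DataFrame({
        "chr": "1",
        "rs": [f"rs{p}" for p in pos],
        "ps": pos,
        "allele1": _BASES[a1],
        "allele0": _BASES[a2],
    })


def generate_fixture(
    n_per_study: int = 2000,
    n_variants: int = 1000,
    overlap_fraction: float = 0.1,
    h2_snp: float = 0.0,
    seed: int = 0,
    out_dir: str = ".",
    flip_fraction: float = 0.5,
) -> dict:
    """Write two GEMMA-dialect summary files with known latent overlap.

    Returns the manifest (also written to ``manifest.json`` in ``out_dir``):
    file paths, true overlap correlation, and — when ``h2_snp > 0`` — the
    causal variant's index, position and true allelic effect.
    """
    if not (0 <= overlap_fraction <= 1):
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_overlap = int(round(overlap_fraction * n_per_study))
    pool = 2 * n_per_study - n_overlap
    g, mafs = simmod.simulate_genotypes(pool, n_variants, rng=rng)
    variants = _variant_frame(n_variants, rng)

    if h2_snp > 0:
        causal = int(rng.integers(0, n_variants))
        spec = simmod.SingleSnpTrait(causal, h2_snp)
        true_beta = simmod.effect_size_for_h2(float(mafs[causal]), h2_snp)
    else:
        causal, true_beta = None, None
        spec = simmod.NullTrait()
    y = simmod.simulate_phenotype(g, spec, mafs, rng)
    s1, s2 = simmod.draw_overlapping_studies(
        pool, n_per_study, n_per_study, n_overlap, rng
    )

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for tag, idx in (("study1", s1), ("study2", s2)):
        assoc = simmod.associate_ols(g[idx], y[idx])
        out = variants.copy()
        out["af"] = g[idx].mean(axis=0) / 2.0
        out["beta"] = assoc["BETA"]
        out["se"] = assoc["SE"]
        out["p_lrt"] = assoc["P"]
        if tag == "study2" and flip_fraction > 0:
            flip = rng.random(n_variants) < flip_fraction
            out.loc[flip, ["allele1", "allele0"]] = (
                out.loc[flip, ["allele0", "allele1"]].to_numpy()
            )
            out.loc[flip, "af"] = 1.0 - out.loc[flip, "af"]
            out.loc[flip, "beta"] = -out.loc[flip, "beta"]
        path = os.path.join(out_dir, f"{tag}.sumstats.txt")
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths.append(path)

    manifest = {
        "files": paths,
        "n_per_study": n_per_study,
        "n_variants": n_variants,
        "n_overlap": n_overlap,
        "true_correlation": corrmod.expected_correlation_from_overlap(
            n_overlap, n_per_study, n_per_study
        ),
        "h2_snp": h2_snp,
        "causal_index": causal,
        "causal_pos": (int(variants["ps"].iloc[causal])
                       if causal is not None else None),
        "true_beta": true_beta,
        "seed": seed,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def run_pipeline(
    paths: list[str],
    out_path: str,
    dialect: str | dict = "gemma",
    n_default: float | None = None,
    correlation: str = "tetrachoric",
    cap: float = corrmod.DEFAULT_CAP,
    min_studies: int = 1,
    thin: int = 1,
) -> pd.DataFrame:
    """Read studies, harmonize, estimate correlation, meta-analyse, write.

    ``correlation`` is one of ``tetrachoric``, ``pearson``, ``none``,
    ``matrix:<file>`` or ``overlap:<n0>`` (K=2 only for the overlap form).
    Returns the result table, which is also written to ``out_path``.
    """
    studies = [sumstats.read_summary(p, dialect=dialect, n_default=n_default)
               for p in paths]
    panel = sumstats.harmonize(studies)
    k = panel.k
    if correlation == "none":
        corr = corrmod.StudyCorrelation(np.eye(k), "user", panel.studies)
    elif correlation in {"tetrachoric", "pearson"}:
        corr = corrmod.estimate_study_correlation(
            panel, method=correlation, cap=cap, thin=thin
        )
    elif correlation.startswith("matrix:"):
        corr = corrmod.read_correlation_matrix(correlation.split(":", 1)[1])
        if corr.k != k:
            raise ValueError("correlation matrix dimension != study count")
    elif correlation.startswith("overlap:"):
        n0s = [float(x) for x in correlation.split(":", 1)[1].split(",")]
        if k != 2 or len(n0s) != 1:
            raise ValueError("overlap:<n0> supports exactly 2 studies")
        ns = [s.n_total for s in studies]
        if any(n is None for n in ns):
            raise ValueError("overlap correlation needs per-study n "
                             "(pass n_default)")
        r = corrmod.expected_correlation_from_overlap(n0s[0], ns[0], ns[1])
        mat = np.array([[1.0, r], [r, 1.0]])
        corr = corrmod.StudyCorrelation(mat, "expected_overlap",
                                        panel.studies)
    else:
        raise ValueError(f"unknown correlation spec {correlation!r}")

    logger.info("inter-study correlation (%s):\n%s", corr.method, corr.matrix)
    results = metamod.meta_analyse(panel, corr, min_studies=min_studies)
    sumstats.write_meta(results, out_path)
    return results
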