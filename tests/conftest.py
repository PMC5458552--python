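import numpy as np
import pandas as pd
import pytest

from overlapmeta.sumstats import FIELDS, StudySummary


def make_study(study_id, n_variants=20, seed=0, n=1000, chrom="1",
               variant_seed=1234):
    """Small random but valid StudySummary for unit tests.

    ``variant_seed`` controls positions/alleles; keeping it fixed across
    studies makes their variants match, while ``seed`` varies the statistics.
    """
    vrng = np.random.default_rng(variant_seed)
    rng = np.random.default_rng(seed)
    pos = np.arange(1, n_variants + 1) * 1000
    bases = np.array(list("ACGT"))
    a1 = vrng.integers(0, 4, n_variants)
    a2 = (a1 + vrng.integers(1, 4, n_variants)) % 4
    beta = rng.normal(0, 0.1, n_variants)
    se = rng.uniform(0.02, 0.2, n_variants)
    from scipy import stats

    p = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    table = pd.DataFrame({
        "CHROM": chrom, "POS": pos, "EA": bases[a1], "NEA": bases[a2],
        "EAF": rng.uniform(0.05, 0.95, n_variants),
        "BETA": beta, "SE": se, "P": p,
        "N": float(n),
    })
    return StudySummary(study_id=study_id, n_total=float(n), table=table[FIELDS])


def flip_study(study, mask=None):
    """Copy of a study with (a subset of) rows in the swapped orientation."""
    t = study.table.copy()
    if mask is None:
        mask = np.ones(len(t), dtype=bool)
    t.loc[mask, ["EA", "NEA"]] = t.loc[mask, ["NEA", "EA"]].to_numpy()
    t.loc[mask, "BETA"] = -t.loc[mask, "BETA"]
    t.loc[mask, "EAF"] = 1.0 - t.loc[mask, "EAF"]
    return StudySummary(study_id=study.study_id, n_total=study.n_total,
                        table=t)


@pytest.fixture
def gemma_file(tmp_path):
    """Three-row GEMMA-dialect summary file."""
    path = tmp_path / "study.assoc.txt"
    path.write_text(
        "chr\trs\tps\tallele1\tallele0\taf\tbeta\tse\tp_lrt\n"
        "1\trs1\t1000\tA\tG\t0.1\t0.5\t0.1\t1e-6\n"
        "1\trs2\t2000\tC\tT\t0.4\t-0.2\t0.05\t0.02\n"
        "2\trs3\t500\tG\tC\t0.25\t0.01\t0.02\t0.9\n"
    )
    return path
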