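"""Reading, validation and harmonization of per-study GWAS summary statistics.

A study is a table of per-variant association results: effect size (beta, in
trait-SD units per copy of the effect allele), its standard error, a two-sided
p-value, the effect-allele frequency and a per-variant sample size. Studies
are aligned on (chromosome, position, allele set); when a study reports the
same variant with swapped effect/other alleles, its beta is negated and the
frequency complemented so that all studies share one orientation.

Coordinates are 1-based (GRCh37-style labels); inputs are assumed same-strand.
Palindromic (A/T, C/G) variants are matched like any other, but a counter of
them is kept so the caller can be warned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for a study table
FIELDS = ["CHROM", "POS", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]

#: built-in column dialects, mapping logical field -> column name in the file
DIALECTS: dict[str, dict[str, str]] = {
    "gemma": {
        "chrom": "chr",
        "pos": "ps",
        "ea": "allele1",
        "nea": "allele0",
        "eaf": "af",
        "beta": "beta",
        "se": "se",
        "p": "p_lrt",
    },
    "generic": {
        "chrom": "CHR",
        "pos": "POS",
        "ea": "EA",
        "nea": "NEA",
        "eaf": "EAF",
        "beta": "BETA",
        "se": "SE",
        "p": "P",
        "n": "N",
    },
}

#: columns written by :func:`write_meta`
META_COLUMNS = [
    "CHROM", "POS", "EA", "NEA", "N_STUDIES", "N_TOTAL",
    "Z_UNCORR", "P_Z_UNCORR", "Z_CORR", "P_Z_CORR",
    "BETA_UNCORR", "SE_UNCORR", "P_B_UNCORR",
    "BETA_CORR", "SE_CORR", "P_B_CORR",
]

_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class SumstatsFormatError(ValueError):
    """The file does not match the declared column dialect."""


class SumstatsDataError(ValueError):
    """The file parses but contains invalid or contradictory records."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of a biallelic variant: position plus unordered allele pair."""

    chrom: str
    pos: int
    ea: str
    nea: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome label")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ea or not self.nea or self.ea == self.nea:
            raise ValueError(f"invalid allele pair {self.ea}/{self.nea}")

    def matches(self, other: "VariantKey") -> bool:
        """Same variant irrespective of which allele is labelled 'effect'."""
        return (
            self.chrom == other.chrom
            and self.pos == other.pos
            and {self.ea, self.nea} == {other.ea, other.nea}
        )

    def is_flipped_relative_to(self, other: "VariantKey") -> bool:
        return self.matches(other) and self.ea != other.ea

    @property
    def palindromic(self) -> bool:
        return frozenset({self.ea, self.nea}) in _PALINDROMIC


@dataclass(frozen=True)
class AssocRecord:
    """One study's association result at one variant."""

    key: VariantKey
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("nonpositive SE")
        if not (0 < self.pvalue <= 1):
            raise ValueError("p out of range")
        if not (0 <= self.eaf <= 1):
            raise ValueError("eaf out of range")
        if not self.n >= 1:
            raise ValueError("invalid n")

    def flipped(self) -> "AssocRecord":
        """Same record with the opposite allele labelled 'effect'."""
        return AssocRecord(
            key=VariantKey(self.key.chrom, self.key.pos,
                           self.key.nea, self.key.ea),
            eaf=1.0 - self.eaf, beta=-self.beta, se=self.se,
            pvalue=self.pvalue, n=self.n,
        )


@dataclass
class StudySummary:
    """One study's summary statistics.

    ``table`` has columns CHROM POS EA NEA EAF BETA SE P N and a default
    RangeIndex; no two rows share the same (CHROM, POS, allele-set) key.
    """

    study_id: str
    n_total: float | None
    table: pd.DataFrame
    n_rejected: int = 0
    reject_reasons: pd.Series | None = None

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AlignedPanel:
    """Per-variant records of K studies in one shared allele orientation.

    ``variants`` carries the key columns CHROM POS EA NEA plus, for each
    study, EAF/BETA/SE/P/N columns suffixed ``:<study_id>`` (NaN where the
    study lacks the variant).
    """

    studies: list[str]
    variants: pd.DataFrame
    n_dropped_incompatible: int = 0
    n_palindromic: int = 0

    @property
    def k(self) -> int:
        return len(self.studies)

    def study_columns(self, field_name: str) -> list[str]:
        return [f"{field_name}:{s}" for s in self.studies]

    def presence(self) -> np.ndarray:
        """Boolean (n_variants, K) matrix of which study carries which row."""
        return self.variants[self.study_columns("BETA")].notna().to_numpy()


def _allele_norm(s: pd.Series) -> pd.Series:
    return s.astype(str).str.upper().str.strip()


def read_summary(
    path,
    dialect: str | dict[str, str] = "generic",
    n_default: float | None = None,
    study_id: str | None = None,
) -> StudySummary:
    """Read one study's summary statistics from delimited text.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited file with a header line.
    dialect
        Name of a built-in dialect (``"gemma"``, ``"generic"``) or a mapping
        from logical fields {chrom,pos,ea,nea,eaf,beta,se,p[,n]} to column
        names.
    n_default
        Per-variant sample size to use when the dialect has no ``n`` column
        (or the column is missing values). Required for the GEMMA dialect.
    study_id
        Defaults to the file's stem.

    Rows violating the record invariants (nonpositive SE, p outside (0, 1],
    frequency outside [0, 1], nonpositive n) are rejected individually and
    counted; a zero p-value is a hard error because the z-transform is
    undefined for it.
    """
    if isinstance(dialect, str):
        try:
            colmap = DIALECTS[dialect]
        except KeyError:
            raise SumstatsFormatError(f"unknown dialect {dialect!r}") from None
    else:
        colmap = dict(dialect)

    required = {"chrom", "pos", "ea", "nea", "eaf", "beta", "se", "p"}
    missing_logical = required - set(colmap)
    if missing_logical:
        raise SumstatsFormatError(
            f"dialect lacks mappings for {sorted(missing_logical)}"
        )

    raw = pd.read_csv(path, sep=r"\s+", dtype={colmap["chrom"]: str})
    missing_cols = [c for f, c in colmap.items() if c not in raw.columns]
    if missing_cols:
        raise SumstatsFormatError(
            f"{path}: header lacks mapped column(s) {missing_cols}"
        )

    df = pd.DataFrame(
        {
            "CHROM": raw[colmap["chrom"]].astype(str).str.strip(),
            "POS": pd.to_numeric(raw[colmap["pos"]], errors="coerce"),
            "EA": _allele_norm(raw[colmap["ea"]]),
            "NEA": _allele_norm(raw[colmap["nea"]]),
            "EAF": pd.to_numeric(raw[colmap["eaf"]], errors="coerce"),
            "BETA": pd.to_numeric(raw[colmap["beta"]], errors="coerce"),
            "SE": pd.to_numeric(raw[colmap["se"]], errors="coerce"),
            "P": pd.to_numeric(raw[colmap["p"]], errors="coerce"),
        }
    )
    if "n" in colmap and colmap["n"] in raw.columns:
        df["N"] = pd.to_numeric(raw[colmap["n"]], errors="coerce")
    else:
        df["N"] = np.nan
    if n_default is not None:
        df["N"] = df["N"].fillna(float(n_default))

    if (df["P"] == 0).any():
        bad = df.index[df["P"] == 0][0]
        raise SumstatsDataError(
            f"{path}: p = 0 at row {bad}; log-space p input is unsupported — "
            "supply the smallest representable p instead"
        )

    reasons = pd.Series("", index=df.index, dtype=object)

    def _flag(mask: pd.Series, reason: str) -> None:
        mask = mask.fillna(False) if mask.dtype == object else mask
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    _flag(~(df["POS"] >= 1) | df["POS"].isna(), "invalid position")
    _flag((df["EA"] == df["NEA"]) | (df["EA"] == "") | (df["NEA"] == ""),
          "invalid alleles")
    _flag(~(df["SE"] > 0), "nonpositive SE")
    _flag(~((df["P"] > 0) & (df["P"] <= 1)), "p out of range")
    _flag(~((df["EAF"] >= 0) & (df["EAF"] <= 1)), "eaf out of range")
    _flag(~(df["N"] >= 1), "invalid n")
    _flag(df["BETA"].isna(), "missing beta")

    bad = reasons != ""
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.warning(
            "%s: rejected %d row(s): %s", path, n_rejected,
            reasons[bad].value_counts().to_dict(),
        )
    df = df[~bad].reset_index(drop=True)
    df["POS"] = df["POS"].astype(np.int64)

    allele_set = _allele_key(df["EA"], df["NEA"])
    dup = df.assign(ALLELES=allele_set).duplicated(
        subset=["CHROM", "POS", "ALLELES"], keep=False
    )
    if dup.any():
        r = df[dup].iloc[0]
        raise SumstatsDataError(
            f"{path}: duplicate variant {r['CHROM']}:{r['POS']} "
            f"{r['EA']}/{r['NEA']}"
        )

    sid = study_id if study_id is not None else _stem(path)
    return StudySummary(
        study_id=sid,
        n_total=n_default,
        table=df[FIELDS],
        n_rejected=n_rejected,
        reject_reasons=reasons[bad] if n_rejected else None,
    )


def _allele_key(ea: pd.Series, nea: pd.Series) -> list[str]:
    """Orientation-free allele-set key, sortable and hashable."""
    return ["|".join(sorted(pair)) for pair in zip(ea, nea)]


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_summary(study: StudySummary, path) -> None:
    """Write a study back out in the 'generic' dialect (TSV)."""
    out = study.table.rename(
        columns={"CHROM": "CHR"}
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def harmonize(studies: list[StudySummary]) -> AlignedPanel:
    """Align K studies to one panel with a common effect-allele orientation.

    Variants are matched on (chromosome, position, unordered allele set). The
    orientation of the first study carrying a variant wins; a study reporting
    the swapped orientation has its beta negated and eaf complemented. A study
    reporting a different allele set at the same position contributes nothing
    for that variant (the drop is counted, not fatal).
    """
    if not studies:
        raise ValueError("need at least one study")
    ids = [s.study_id for s in studies]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate study ids in {ids}")

    frames = []
    for s in studies:
        t = s.table.copy()
        t["ALLELES"] = _allele_key(t["EA"], t["NEA"])
        frames.append(t.set_index(["CHROM", "POS", "ALLELES"]))

    # orientation reference: first study (in input order) carrying each key
    ref = frames[0][["EA", "NEA"]]
    for t in frames[1:]:
        extra = t.loc[~t.index.isin(ref.index), ["EA", "NEA"]]
        ref = pd.concat([ref, extra])
    ref = ref.sort_index()

    panel = ref.reset_index()[["CHROM", "POS"]].copy()
    panel["EA"] = ref["EA"].to_numpy()
    panel["NEA"] = ref["NEA"].to_numpy()
    panel.index = ref.index

    # a study whose allele set disagrees with every other study at a shared
    # position never joins the other studies' row; the key includes alleles,
    # so its record survives as a distinct variant rather than vanishing.
    pos_level = ref.index.droplevel("ALLELES")
    n_mismatch_pos = int(pos_level.duplicated().sum())
    if n_mismatch_pos:
        logger.warning(
            "%d position(s) carry >1 distinct allele set across studies; "
            "kept as distinct variants", n_mismatch_pos,
        )

    pal = {"A|T", "C|G"}
    n_pal = int(sum(a in pal for a in ref.index.get_level_values("ALLELES")))
    if n_pal:
        logger.warning(
            "%d palindromic (A/T or C/G) variant(s); strand flips cannot be "
            "detected for these", n_pal,
        )

    for sid, t in zip(ids, frames):
        aligned = t.reindex(ref.index)
        flip = aligned["EA"].notna() & (aligned["EA"] != ref["EA"])
        aligned.loc[flip, "BETA"] = -aligned.loc[flip, "BETA"]
        aligned.loc[flip, "EAF"] = 1.0 - aligned.loc[flip, "EAF"]
        for f in ["EAF", "BETA", "SE", "P", "N"]:
            panel[f"{f}:{sid}"] = aligned[f].to_numpy()

    panel = panel.reset_index(drop=True)
    return AlignedPanel(
        studies=ids,
        variants=panel,
        n_dropped_incompatible=n_mismatch_pos,
        n_palindromic=n_pal,
    )


def panel_to_summaries(panel: AlignedPanel) -> list[StudySummary]:
    """Decompose a panel back into per-study summaries (harmonized rows)."""
    out = []
    for sid in panel.studies:
        cols = {f: f"{f}:{sid}" for f in ["EAF", "BETA", "SE", "P", "N"]}
        t = panel.variants[["CHROM", "POS", "EA", "NEA"] + list(cols.values())]
        t = t.rename(columns={v: k for k, v in cols.items()})
        t = t.dropna(subset=["BETA"]).reset_index(drop=True)
        out.append(StudySummary(study_id=sid, n_total=None, table=t[FIELDS]))
    return out


def write_meta(results: pd.DataFrame, path) -> None:
    """Write meta-analysis results as TSV with the documented header.

    ``results`` must carry :data:`META_COLUMNS`. Values round-trip through
    :func:`read_meta` to 12 significant digits.
    """
    if results is None or len(results) == 0:
        raise ValueError("no results to write")
    missing = [c for c in META_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results lack column(s) {missing}")
    results[META_COLUMNS].to_csv(path, sep="\t", index=False,
                                 float_format="%.12g")


def read_meta(path) -> pd.DataFrame:
    """Read back a file produced by :func:`write_meta`."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: lacks column(s) {missing}")
    return df
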