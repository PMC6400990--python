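"""Read, validate, QC-filter, harmonise and write GWAS summary statistics.

The on-disk dialect is a tab-separated table with the canonical header

    SNP  CHR  POS  EA  OA  EAF  BETA  SE  Z  P  N  INFO  HWE_P

(``INFO`` and ``HWE_P`` optional), ``NA`` as the missing-value token and
transparent gzip support.  Foreign headers are mapped through a *dialect*
dictionary ``{canonical: foreign}``.  Coordinates are 1-based inclusive,
the usual GWAS summary-statistic convention.

Missing statistics are reconstructed from algebraic identities where
possible: ``z = beta/se``, ``se = |beta/z|`` and ``p`` from the two-sided
normal tail of ``z``.
"""
from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import z_to_p

__all__ = [
    "SummaryStatRow",
    "StudySumstats",
    "ReadReport",
    "QCRules",
    "QCReport",
    "SumstatsFormatError",
    "IncompatibleVariantError",
    "read_sumstats",
    "write_sumstats",
    "qc_filter",
    "harmonize_pair",
    "harmonize_tables",
    "CANONICAL_HEADER",
]

CANONICAL_HEADER = [
    "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "Z", "P", "N",
    "INFO", "HWE_P",
]
_HEADER_TO_FIELD = {
    "SNP": "snp", "CHR": "chrom", "POS": "pos", "EA": "ea", "OA": "oa",
    "EAF": "eaf", "BETA": "beta", "SE": "se", "Z": "z", "P": "p", "N": "n",
    "INFO": "info", "HWE_P": "hwe_p",
}
_FIELD_TO_HEADER = {v: k for k, v in _HEADER_TO_FIELD.items()}
_MANDATORY = ["snp", "chrom", "pos", "ea", "oa"]
_NUMERIC = ["pos", "eaf", "beta", "se", "z", "p", "n", "info", "hwe_p"]

# SNV/indel alleles as plain sequence, or the I/D/R indel tokens.
_ALLELE_RE = re.compile(r"^(?:[ACGT]+|[IDR])$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SumstatsFormatError(ValueError):
    """File-level problem: missing mandatory column, unreadable header."""


class IncompatibleVariantError(ValueError):
    """Allele sets cannot be reconciled by match, flip or strand flip."""


@dataclass
class SummaryStatRow:
    """One variant's association record."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float = np.nan
    beta: float = np.nan
    se: float = np.nan
    z: float = np.nan
    p: float = np.nan
    n: float = np.nan
    info: float = np.nan
    hwe_p: float = np.nan

    def is_palindromic(self) -> bool:
        a, b = self.effect_allele, self.other_allele
        return {a, b} in ({"A", "T"}, {"C", "G"})


@dataclass
class ReadReport:
    """Per-file parse outcome: rejected rows are counted, never silent."""

    n_parsed: int = 0
    n_rejected: int = 0
    messages: list = field(default_factory=list)


@dataclass
class StudySumstats:
    """A study's summary statistics backed by a pandas DataFrame.

    ``df`` columns: snp, chrom, pos, ea, oa, eaf, beta, se, z, p, n,
    info, hwe_p.  ``variant_id`` is unique within a study.
    """

    study_id: str
    trait: str
    df: pd.DataFrame
    n_total: int = 0
    genome_build: str = "GRCh37"
    report: ReadReport | None = None

    def __post_init__(self):
        if self.n_total == 0 and len(self.df) and self.df["n"].notna().any():
            self.n_total = int(np.nanmax(self.df["n"].to_numpy(dtype=float)))

    def __len__(self) -> int:
        return len(self.df)

    def rows(self) -> Iterator[SummaryStatRow]:
        for rec in self.df.itertuples(index=False):
            yield SummaryStatRow(
                variant_id=rec.snp, chrom=str(rec.chrom), pos=int(rec.pos),
                effect_allele=rec.ea, other_allele=rec.oa,
                eaf=rec.eaf, beta=rec.beta, se=rec.se, z=rec.z, p=rec.p,
                n=rec.n, info=rec.info, hwe_p=rec.hwe_p,
            )

    def row(self, variant_id: str) -> SummaryStatRow:
        sub = self.df[self.df["snp"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        return next(StudySumstats(self.study_id, self.trait, sub).rows())


def _empty_frame() -> pd.DataFrame:
    df = pd.DataFrame(
        {f: pd.Series(dtype=("object" if f in ("snp", "chrom", "ea", "oa")
                             else "float64"))
         for f in _HEADER_TO_FIELD.values()}
    )
    return df


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    study_id: str = "study",
    trait: str = "trait",
    n_total: int = 0,
    genome_build: str = "GRCh37",
) -> StudySumstats:
    """Read a summary-statistic TSV into a :class:`StudySumstats`.

    ``dialect`` maps canonical header names (``SNP``, ``CHR``, ...) to the
    column names actually present in the file.  Rows violating parse rules
    (unparseable numerics, invalid or multi-allelic alleles, frequencies
    outside [0,1], duplicate IDs) are removed, counted and listed with
    line numbers in the returned ``report``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                      keep_default_na=False, compression="infer")
    dialect = dict(dialect or {})
    colmap = {}
    for canon, fld in _HEADER_TO_FIELD.items():
        src = dialect.get(canon, canon)
        if src in raw.columns:
            colmap[fld] = src
    missing = [f for f in _MANDATORY if f not in colmap]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing mandatory column(s) "
            f"{[_FIELD_TO_HEADER[f] for f in missing]}; header = {list(raw.columns)}"
        )

    report = ReadReport()
    df = pd.DataFrame({fld: raw[src] for fld, src in colmap.items()})
    for fld in _HEADER_TO_FIELD.values():
        if fld not in df.columns:
            df[fld] = np.nan

    bad = np.zeros(len(df), dtype=bool)

    def _reject(mask: np.ndarray, why: str) -> None:
        mask = np.asarray(mask, dtype=bool) & ~bad
        for i in np.flatnonzero(mask):
            # +2: header line plus 1-based numbering
            report.messages.append(f"line {i + 2}: {why}")
        bad[mask] = True

    for fld in _NUMERIC:
        src = df[fld]
        if src.dtype == object:
            num = pd.to_numeric(src, errors="coerce")
            _reject(num.isna() & src.notna(), f"unparseable numeric in {_FIELD_TO_HEADER[fld]}")
            df[fld] = num
        else:
            df[fld] = pd.to_numeric(src, errors="coerce")

    for fld, label in (("ea", "EA"), ("oa", "OA")):
        al = df[fld].astype(str).str.upper()
        df[fld] = al
        _reject(df[fld].isna() | (al == "NAN"), f"missing allele {label}")
        _reject(al.str.contains(",", na=False), f"multi-allelic {label} rejected")
        ok = al.str.match(_ALLELE_RE.pattern, na=False)
        _reject(~ok & ~al.str.contains(",", na=False), f"invalid allele token in {label}")
    _reject(df["snp"].isna(), "missing variant ID")
    _reject(df["pos"].isna(), "missing or unparseable position")
    _reject((df["eaf"] < 0) | (df["eaf"] > 1), "EAF outside [0,1]")
    _reject((df["p"] <= 0) | (df["p"] > 1), "p outside (0,1]")
    _reject(df["snp"].duplicated(keep="first"), "duplicate variant ID")

    report.n_rejected = int(bad.sum())
    df = df.loc[~bad].reset_index(drop=True)
    report.n_parsed = len(df)

    # reconstruct missing statistics from identities
    with np.errstate(divide="ignore", invalid="ignore"):
        need_se = df["se"].isna() & df["beta"].notna() & df["z"].notna() & (df["z"] != 0)
        df.loc[need_se, "se"] = (df.loc[need_se, "beta"] / df.loc[need_se, "z"]).abs()
        inconsistent = (
            df["se"].notna() & df["beta"].notna() & df["z"].notna()
            & ((df["z"] - df["beta"] / df["se"]).abs() >= 1e-6)
        )
        if inconsistent.any():
            report.messages.append(
                f"{int(inconsistent.sum())} row(s) with Z inconsistent with BETA/SE; "
                "Z recomputed from BETA/SE"
            )
            df.loc[inconsistent, "z"] = np.nan
        need_z = df["z"].isna() & df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
        df.loc[need_z, "z"] = df.loc[need_z, "beta"] / df.loc[need_z, "se"]
    need_p = df["p"].isna() & df["z"].notna()
    if need_p.any():
        df.loc[need_p, "p"] = z_to_p(df.loc[need_p, "z"].to_numpy())

    df["chrom"] = df["chrom"].astype(str)
    if df.empty:
        df = _empty_frame()
    return StudySumstats(study_id=study_id, trait=trait, df=df,
                         n_total=n_total, genome_build=genome_build,
                         report=report)


def write_sumstats(study: StudySumstats, path) -> None:
    """Write in the canonical dialect; ``read_sumstats`` round-trips it."""
    out = pd.DataFrame({h: study.df[_HEADER_TO_FIELD[h]] for h in CANONICAL_HEADER})
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class QCRules:
    """Variant-level exclusion thresholds applied independently.

    A non-positive SE is excluded along with SE above ``se_max``: an SE of
    zero would give every downstream inverse-variance weight infinite mass.
    INFO thresholds are per-study configuration (imputation pipelines
    differ), default 0.4.
    """

    se_max: float = 10.0
    beta_abs_max: float = 5.0
    hwe_p_min: float = 1e-6
    info_min: float = 0.4


@dataclass
class QCReport:
    n_in: int
    n_out: int
    counts: dict
    skipped: dict


def qc_filter(study: StudySumstats, rules: QCRules | None = None):
    """Apply variant QC; returns ``(filtered study, QCReport)``.

    Rules are applied independently: a row failing two rules is counted
    under both and removed once.  A row missing the field a rule needs
    skips that rule (counted in ``report.skipped``).
    """
    rules = rules or QCRules()
    df = study.df
    checks = {
        "se": (df["se"] > rules.se_max) | (df["se"] <= 0),
        "beta": df["beta"].abs() > rules.beta_abs_max,
        "hwe_p": df["hwe_p"] < rules.hwe_p_min,
        "info": df["info"] < rules.info_min,
    }
    fields = {"se": "se", "beta": "beta", "hwe_p": "hwe_p", "info": "info"}
    drop = np.zeros(len(df), dtype=bool)
    counts, skipped = {}, {}
    for name, mask in checks.items():
        mask = mask.fillna(False).to_numpy(dtype=bool)
        counts[name] = int(mask.sum())
        skipped[name] = int(df[fields[name]].isna().sum())
        drop |= mask
    out = dataclasses.replace(
        study, df=df.loc[~drop].reset_index(drop=True), report=None
    )
    return out, QCReport(n_in=len(df), n_out=len(out.df), counts=counts,
                         skipped=skipped)


def _flip_row(b: SummaryStatRow) -> SummaryStatRow:
    return dataclasses.replace(
        b,
        effect_allele=b.other_allele,
        other_allele=b.effect_allele,
        eaf=(1.0 - b.eaf) if np.isfinite(b.eaf) else b.eaf,
        beta=-b.beta if np.isfinite(b.beta) else b.beta,
        z=-b.z if np.isfinite(b.z) else b.z,
    )


def _strand_flip_row(b: SummaryStatRow) -> SummaryStatRow:
    return dataclasses.replace(
        b,
        effect_allele=b.effect_allele.translate(_COMPLEMENT),
        other_allele=b.other_allele.translate(_COMPLEMENT),
    )


def _can_complement(row: SummaryStatRow) -> bool:
    return bool(re.fullmatch(r"[ACGT]+", row.effect_allele)
                and re.fullmatch(r"[ACGT]+", row.other_allele))


def harmonize_pair(a: SummaryStatRow, b: SummaryStatRow,
                   ambiguity_maf: float = 0.40):
    """Align ``b``'s effect allele to ``a``'s.

    Returns ``(a, b_aligned, tag)`` with tag one of ``identity``,
    ``flipped``, ``strand``, ``strand-flipped`` or ``ambiguous-dropped``.
    Palindromic (A/T, C/G) variants whose minor-allele frequency exceeds
    ``ambiguity_maf`` in either row cannot be strand-resolved from
    frequency and are tagged ``ambiguous-dropped`` (``b`` returned
    unchanged).  Raises :class:`IncompatibleVariantError` if no match,
    flip or strand flip reconciles the allele sets.
    """
    if a.is_palindromic() or b.is_palindromic():
        for r in (a, b):
            if np.isfinite(r.eaf) and min(r.eaf, 1 - r.eaf) > ambiguity_maf:
                return a, b, "ambiguous-dropped"
    if (b.effect_allele, b.other_allele) == (a.effect_allele, a.other_allele):
        return a, b, "identity"
    if (b.effect_allele, b.other_allele) == (a.other_allele, a.effect_allele):
        return a, _flip_row(b), "flipped"
    if _can_complement(b):
        bc = _strand_flip_row(b)
        if (bc.effect_allele, bc.other_allele) == (a.effect_allele, a.other_allele):
            return a, bc, "strand"
        if (bc.effect_allele, bc.other_allele) == (a.other_allele, a.effect_allele):
            return a, _flip_row(bc), "strand-flipped"
    raise IncompatibleVariantError(
        f"{a.variant_id}: alleles {a.effect_allele}/{a.other_allele} vs "
        f"{b.effect_allele}/{b.other_allele} cannot be reconciled"
    )


def harmonize_tables(exposure: pd.DataFrame, outcome: pd.DataFrame,
                     ambiguity_maf: float = 0.40) -> pd.DataFrame:
    """Join exposure and outcome summary statistics on variant ID and
    align the outcome rows to the exposure orientation.

    Both inputs use the internal column names (``snp, ea, oa, eaf, beta,
    se, ...``).  Returns one row per shared, reconcilable variant with
    columns ``snp, ea, oa, eaf, gamma_x, se_x, Gamma_y, se_y, action``;
    ambiguous palindromic and irreconcilable variants are excluded with
    actions recorded in ``result.attrs['dropped']``.
    """
    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
    rows, dropped = [], []
    for rec in merged.itertuples(index=False):
        a = SummaryStatRow(rec.snp, str(rec.chrom_x), int(rec.pos_x),
                           rec.ea_x, rec.oa_x, eaf=rec.eaf_x,
                           beta=rec.beta_x, se=rec.se_x, z=rec.z_x,
                           p=rec.p_x, n=rec.n_x)
        b = SummaryStatRow(rec.snp, str(rec.chrom_y), int(rec.pos_y),
                           rec.ea_y, rec.oa_y, eaf=rec.eaf_y,
                           beta=rec.beta_y, se=rec.se_y, z=rec.z_y,
                           p=rec.p_y, n=rec.n_y)
        try:
            a, b2, tag = harmonize_pair(a, b, ambiguity_maf=ambiguity_maf)
        except IncompatibleVariantError:
            dropped.append((rec.snp, "incompatible"))
            continue
        if tag == "ambiguous-dropped":
            dropped.append((rec.snp, tag))
            continue
        rows.append({"snp": rec.snp, "ea": a.effect_allele,
                     "oa": a.other_allele, "eaf": a.eaf,
                     "gamma_x": a.beta, "se_x": a.se,
                     "Gamma_y": b2.beta, "se_y": b2.se, "action": tag})
    out = pd.DataFrame(rows, columns=["snp", "ea", "oa", "eaf", "gamma_x",
                                      "se_x", "Gamma_y", "se_y", "action"])
    out.attrs["dropped"] = dropped
    return out
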