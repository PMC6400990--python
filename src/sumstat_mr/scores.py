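"""Effect-size-weighted genetic scores and phenome scans.

Scores are built from meta-analysis effect sizes oriented to the
exposure-raising allele, so every weight is non-negative and tiered
subsetting (e.g. a pathway-specific subset of a genome-wide score) is
unambiguous.  A score value for an individual is the weighted allele
count ``sum_j w_j * dosage_j``.

``trait_scan`` regresses each of a panel of standardized traits on the
score (plus covariates) and flags associations at the Bonferroni level
``alpha / m``; the exact threshold is used for decisions, rounding only
for display.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import round_sig, z_to_p

__all__ = ["GeneticScore", "build_score", "score_values", "score_r2",
           "trait_scan", "bonferroni_threshold"]


@dataclass
class GeneticScore:
    """A named set of (variant, effect allele, non-negative weight)."""

    name: str
    variants: pd.DataFrame  # columns: snp, ea, weight
    tier_parent: str | None = None

    def __post_init__(self):
        need = {"snp", "ea", "weight"}
        if not need.issubset(self.variants.columns):
            raise ValueError(f"score table needs columns {sorted(need)}")
        if self.variants["snp"].duplicated().any():
            raise ValueError("duplicate variants in score")
        if not np.isfinite(self.variants["weight"]).all():
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return len(self.variants)

    def is_subset_of(self, other: "GeneticScore") -> bool:
        return set(self.variants["snp"]).issubset(set(other.variants["snp"]))

    def to_frame(self) -> pd.DataFrame:
        out = self.variants.rename(columns={"snp": "SNP", "ea": "EA",
                                            "weight": "WEIGHT"}).copy()
        out["TIER"] = self.name
        return out


def build_score(sumstats: pd.DataFrame, snps: Sequence[str], name: str,
                tier_parent: str | None = None,
                exclude: Sequence[str] = ()) -> GeneticScore:
    """Build a score from summary statistics for the named variants.

    ``sumstats`` needs columns snp, ea, oa, beta (meta-analysis effect
    sizes).  Variants whose listed effect allele lowers the exposure are
    re-oriented (alleles swapped, weight made positive) so all weights
    follow the raising-allele convention.  Variants in ``exclude`` are
    dropped and reported in ``score.variants.attrs['excluded']``.
    """
    exclude = set(exclude)
    rows = []
    excluded = []
    idx = sumstats.set_index("snp")
    for snp in snps:
        if snp in exclude:
            excluded.append(snp)
            continue
        if snp not in idx.index:
            raise KeyError(f"variant {snp} absent from summary statistics")
        rec = idx.loc[snp]
        beta = float(rec["beta"])
        ea = rec["ea"]
        if beta < 0:
            ea = rec["oa"]
            beta = -beta
        rows.append({"snp": snp, "ea": ea, "weight": beta})
    table = pd.DataFrame(rows, columns=["snp", "ea", "weight"])
    table.attrs["excluded"] = excluded
    return GeneticScore(name=name, variants=table, tier_parent=tier_parent)


def score_values(dosages: pd.DataFrame, score: GeneticScore,
                 counted_alleles: Mapping[str, str] | None = None) -> np.ndarray:
    """Per-individual score values from a dosage matrix.

    ``dosages`` has one column per variant ID with values in [0, 2]
    counting ``counted_alleles[snp]`` (defaults to the score's effect
    allele).  Columns counting the other allele are flipped as
    ``2 - dosage``.
    """
    counted_alleles = dict(counted_alleles or {})
    total = np.zeros(len(dosages), dtype=float)
    for rec in score.variants.itertuples(index=False):
        if rec.snp not in dosages.columns:
            raise KeyError(f"dosage column {rec.snp} missing")
        d = dosages[rec.snp].to_numpy(dtype=float)
        counted = counted_alleles.get(rec.snp, rec.ea)
        if counted != rec.ea:
            d = 2.0 - d
        total += rec.weight * d
    return total


def score_r2(values: np.ndarray, phenotype: np.ndarray) -> float:
    """Squared Pearson correlation between score and phenotype."""
    values = np.asarray(values, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if np.std(values) == 0:
        raise ValueError("score has zero variance")
    r = np.corrcoef(values, phenotype)[0, 1]
    return float(r * r)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Exact family-wise threshold ``alpha / m`` (use :func:`round_sig`
    for display)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def trait_scan(values: np.ndarray, traits: pd.DataFrame,
               covariates: pd.DataFrame | None = None,
               alpha: float = 0.05) -> pd.DataFrame:
    """Scan score-trait associations across a trait panel.

    Each trait column is regressed on the score with an intercept and
    optional covariate columns; the per-trait slope, SE, two-sided normal
    p and a Bonferroni significance flag at exact ``alpha / m`` are
    returned.  Constant trait columns are flagged and skipped.
    """
    s = np.asarray(values, dtype=float)
    n = len(s)
    X = [np.ones(n), s]
    if covariates is not None:
        for c in covariates.columns:
            X.append(covariates[c].to_numpy(dtype=float))
    X = np.column_stack(X)
    q = X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    H = xtx_inv @ X.T  # (q, n)

    Y = traits.to_numpy(dtype=float)
    const = np.nanstd(Y, axis=0) == 0
    m = int((~const).sum())
    thresh = bonferroni_threshold(alpha, max(m, 1))

    coefs = H @ Y                       # (q, m_all)
    resid = Y - X @ coefs
    dof = n - q
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    beta = coefs[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = z_to_p(z)

    out = pd.DataFrame({
        "trait": traits.columns,
        "beta": beta, "se": se, "p": p,
        "significant": (p < thresh) & ~const,
        "skipped_constant": const,
    })
    out.loc[const, ["beta", "se", "p"]] = np.nan
    out.attrs["m_tests"] = m
    out.attrs["threshold"] = thresh
    out.attrs["threshold_display"] = round_sig(thresh, 2)
    return out
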