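"""Fixed-effect meta-analysis of per-cohort GWAS statistics.

Two schemes are provided, mirroring the standard multi-cohort workflow
when metabolomics platforms (and hence effect units) differ between
studies:

* a sample-size-weighted Z-score combination (weights sqrt(N), the
  documented default of the standard meta-analysis software), which only
  needs p-values, directions and sample sizes; and
* an inverse-variance-weighted effect-size combination for studies whose
  effects share a unit scale.

Between-study heterogeneity uses Cochran's Q.  Variants poorly shared
across studies are removed by a coverage/MAF filter (present in >= 2
studies, > 50% of the grand total sample, MAF >= 0.1%).
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import z_to_p
from .sumstats import StudySumstats, SummaryStatRow, harmonize_pair, IncompatibleVariantError

__all__ = [
    "stouffer_meta",
    "ivw_effect_meta",
    "cochran_q",
    "coverage_filter",
    "meta_analyze",
]


def stouffer_meta(entries: Sequence[tuple]):
    """Sample-size-weighted Z combination.

    ``entries`` is a sequence of ``(z, n)`` per study in registration
    order; ``z`` may be NaN for a study missing the variant (contributes
    nothing, direction '?').

    Returns ``(z_meta, p_meta, direction)`` with
    ``z_meta = sum(sqrt(n_i) z_i) / sqrt(sum(n_i))`` over contributing
    studies.
    """
    if len(entries) == 0:
        raise ValueError("stouffer_meta needs at least one entry")
    z = np.asarray([e[0] for e in entries], dtype=float)
    n = np.asarray([e[1] for e in entries], dtype=float)
    ok = np.isfinite(z) & np.isfinite(n)
    if not ok.any():
        raise ValueError("no contributing studies")
    if (n[ok] <= 0).any():
        raise ValueError("sample sizes must be positive")
    w = np.sqrt(n[ok])
    z_meta = float(np.sum(w * z[ok]) / np.sqrt(np.sum(n[ok])))
    direction = "".join(
        "?" if not o else ("+" if zi > 0 else ("-" if zi < 0 else "0"))
        for o, zi in zip(ok, z)
    )
    return z_meta, float(z_to_p(z_meta)), direction


def ivw_effect_meta(entries: Sequence[tuple]):
    """Fixed-effect inverse-variance pooling of ``(beta, se)`` pairs."""
    if len(entries) == 0:
        raise ValueError("ivw_effect_meta needs at least one entry")
    beta = np.asarray([e[0] for e in entries], dtype=float)
    se = np.asarray([e[1] for e in entries], dtype=float)
    if (se <= 0).any() or not np.isfinite(se).all():
        raise ValueError("all standard errors must be positive and finite")
    w = 1.0 / se**2
    return float(np.sum(w * beta) / np.sum(w)), float(np.sum(w) ** -0.5)


def cochran_q(entries: Sequence[tuple], pooled_beta: float):
    """Cochran's Q heterogeneity statistic around ``pooled_beta``.

    Returns ``(q, df, q_p)`` with ``q = sum((beta_i - pooled)^2 / se_i^2)``
    and the chi-square upper tail on ``k - 1`` degrees of freedom.
    """
    if len(entries) < 2:
        raise ValueError("cochran_q needs at least two entries")
    beta = np.asarray([e[0] for e in entries], dtype=float)
    se = np.asarray([e[1] for e in entries], dtype=float)
    q = float(np.sum((beta - pooled_beta) ** 2 / se**2))
    df = len(entries) - 1
    return q, df, float(stats.chi2.sf(q, df))


def coverage_filter(meta: pd.DataFrame, n_grand_total: float,
                    maf: Sequence[float] | None = None,
                    min_studies: int = 2, min_n_frac: float = 0.5,
                    min_maf: float = 0.001) -> pd.DataFrame:
    """Restrict meta-analysis results to well-covered variants.

    Keeps rows with ``k_studies >= min_studies``, ``n_total >
    min_n_frac * n_grand_total`` and minor-allele frequency >=
    ``min_maf``.  ``maf`` defaults to ``min(eaf, 1 - eaf)`` of the
    ``eaf`` column.
    """
    if n_grand_total <= 0:
        raise ValueError("n_grand_total must be positive")
    if maf is None:
        maf = np.minimum(meta["eaf"], 1.0 - meta["eaf"])
    maf = np.asarray(maf, dtype=float)
    keep = (
        (meta["k_studies"].to_numpy() >= min_studies)
        & (meta["n_total"].to_numpy(dtype=float) > min_n_frac * n_grand_total)
        & (maf >= min_maf)
    )
    return meta.loc[keep].reset_index(drop=True)


def _aligned_entries(studies: Sequence[StudySumstats]):
    """Yield per-variant lists of rows aligned to the orientation of the
    first study (in registration order) that carries the variant."""
    index: dict[str, list] = {}
    for si, study in enumerate(studies):
        for row in study.rows():
            index.setdefault(row.variant_id, []).append((si, row))
    k = len(studies)
    for vid, hits in index.items():
        ref = hits[0][1]
        aligned: list = [None] * k
        for si, row in hits:
            try:
                _, row2, _ = harmonize_pair(ref, row, ambiguity_maf=1.0)
            except IncompatibleVariantError:
                continue
            aligned[si] = row2
        yield vid, ref, aligned


def meta_analyze(studies: Sequence[StudySumstats],
                 scheme: str = "zscore") -> pd.DataFrame:
    """Meta-analyse several studies variant by variant.

    ``scheme='zscore'`` combines Z statistics with sqrt(N) weights (adds
    beta/se pooling where effects are available, for downstream use);
    ``scheme='ivw'`` pools effect sizes by inverse variance and derives
    Z from the pooled effect.  Studies are harmonised to the orientation
    of the first study carrying each variant; within-variant
    heterogeneity (Q on effects, where >= 2 effects exist) is attached.

    Returns a DataFrame with columns snp, chrom, pos, ea, oa, eaf,
    z_meta, p_meta, beta_meta, se_meta, n_total, k_studies, direction,
    q, q_df, q_p.
    """
    if scheme not in ("zscore", "ivw"):
        raise ValueError(f"unknown scheme {scheme!r}")
    out = []
    for vid, ref, aligned in _aligned_entries(studies):
        zn = [(r.z if r is not None else np.nan,
               r.n if r is not None else np.nan) for r in aligned]
        contributing = [r for r in aligned if r is not None]
        n_total = float(np.nansum([r.n for r in contributing]))
        k = len(contributing)
        # sample-size-weighted mean EAF over contributing studies
        eafs = np.array([r.eaf for r in contributing], dtype=float)
        ns = np.array([r.n for r in contributing], dtype=float)
        ok = np.isfinite(eafs) & np.isfinite(ns)
        eaf = float(np.sum(eafs[ok] * ns[ok]) / np.sum(ns[ok])) if ok.any() else np.nan

        effects = [(r.beta, r.se) for r in contributing
                   if np.isfinite(r.beta) and np.isfinite(r.se) and r.se > 0]
        beta_meta = se_meta = np.nan
        if effects:
            beta_meta, se_meta = ivw_effect_meta(effects)
        q = q_p = np.nan
        q_df = 0
        if len(effects) >= 2:
            q, q_df, q_p = cochran_q(effects, beta_meta)

        z_meta, p_meta, direction = stouffer_meta(zn)
        if scheme == "ivw":
            if not effects:
                continue
            z_meta = beta_meta / se_meta
            p_meta = float(z_to_p(z_meta))
            direction = "".join(
                "?" if r is None or not np.isfinite(r.beta)
                else ("+" if r.beta > 0 else ("-" if r.beta < 0 else "0"))
                for r in aligned
            )
        out.append({
            "snp": vid, "chrom": ref.chrom, "pos": ref.pos,
            "ea": ref.effect_allele, "oa": ref.other_allele, "eaf": eaf,
            "z_meta": z_meta, "p_meta": p_meta,
            "beta_meta": beta_meta, "se_meta": se_meta,
            "n_total": n_total, "k_studies": k, "direction": direction,
            "q": q, "q_df": q_df, "q_p": q_p,
        })
    return pd.DataFrame(out)
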