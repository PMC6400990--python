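"""Sex-stratified effect comparison.

Phenotypes are standardized within sex (each stratum to mean 0, SD 1) so
per-allele effects are in within-sex SD units; the raw per-sex SDs are
returned for converting estimates back to measurement units.  The sex
difference of a variant's effect is tested with

    z_sex = (beta_f - beta_m) / sqrt(se_f^2 + se_m^2)

against the two-sided normal tail.  Summary data give no usable degrees
of freedom and cohort sizes are in the tens of thousands, so the normal
reference is used; the tail is evaluated in log space so even enormous
statistics (|z| well above 60) retain their magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._stats import z_to_log10p, z_to_p
from .meta import ivw_effect_meta

__all__ = ["SexPair", "standardize_by_sex", "sex_diff_test",
           "combine_sex_across_cohorts"]


@dataclass
class SexPair:
    """Female and male effects of one variant, in within-sex SD units."""

    variant_id: str
    beta_f: float
    se_f: float
    beta_m: float
    se_m: float
    z_sex: float = np.nan
    p_sex: float = np.nan
    log10_p_sex: float = np.nan


def standardize_by_sex(values: np.ndarray, sex: Sequence):
    """Z-standardize within each sex stratum.

    Returns ``(standardized values, {sex_label: raw SD})``.  SDs are the
    sample SD (ddof=1), so standardization is idempotent.  Each stratum
    needs at least two distinct values; zero variance is an error.
    """
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    out = np.empty_like(values)
    sds = {}
    for label in np.unique(sex):
        mask = sex == label
        sd = float(np.std(values[mask], ddof=1)) if mask.sum() > 1 else 0.0
        if mask.sum() < 2 or sd == 0:
            raise ValueError(f"stratum {label!r} has no variance")
        out[mask] = (values[mask] - np.mean(values[mask])) / sd
        sds[label] = sd
    return out, sds


def sex_diff_test(beta_f: float, se_f: float, beta_m: float, se_m: float,
                  variant_id: str = "", m_tests: int = 1,
                  alpha: float = 0.05):
    """Test whether a variant's effect differs between the sexes.

    Returns ``(SexPair, significant)`` where significance uses the exact
    Bonferroni threshold ``alpha / m_tests``.  ``p_sex`` may underflow to
    a subnormal/zero double for extreme contrasts; ``log10_p_sex`` always
    carries the magnitude.
    """
    if se_f <= 0 or se_m <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_f - beta_m) / np.hypot(se_f, se_m)
    log10p = float(z_to_log10p(z))
    pair = SexPair(variant_id=variant_id, beta_f=beta_f, se_f=se_f,
                   beta_m=beta_m, se_m=se_m, z_sex=float(z),
                   p_sex=float(z_to_p(z)), log10_p_sex=log10p)
    significant = log10p < np.log10(alpha / m_tests)
    return pair, bool(significant)


def combine_sex_across_cohorts(pairs: Sequence[SexPair],
                               m_tests: int = 1,
                               alpha: float = 0.05):
    """Fixed-effect pooling of per-cohort sex-specific estimates.

    Pools the female and male effects separately by inverse variance,
    then applies :func:`sex_diff_test` to the pooled pair.
    """
    if len(pairs) == 0:
        raise ValueError("no cohorts to combine")
    bf, sf = ivw_effect_meta([(p.beta_f, p.se_f) for p in pairs])
    bm, sm = ivw_effect_meta([(p.beta_m, p.se_m) for p in pairs])
    vid = pairs[0].variant_id
    return sex_diff_test(bf, sf, bm, sm, variant_id=vid,
                         m_tests=m_tests, alpha=alpha)
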