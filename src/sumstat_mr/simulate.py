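"""Ground-truth cohort and summary-statistic simulation.

Every pipeline stage in this package is exercised against synthetic
cohorts with known generative parameters, built to mimic the statistical
structure of multi-cohort metabolite GWAS:

* LD-blocked diploid genotypes: within a block, the two haplotype
  alleles of each individual share a latent Gaussian with correlation
  ``rho`` thresholded at the MAF quantile, so block LD is controlled
  analytically (the attenuation between latent ``rho`` and realized
  dosage ``r`` follows the bivariate-normal orthant probability and is
  characterised by an oracle test, not assumed);
* a log-normally distributed metabolite driven by one dominant locus
  plus a polygenic background, with sex-dimorphic per-allele effects
  (within-sex SD units) and sex-specific raw-scale spreads;
* a disease outcome generated on a liability scale with a configurable
  causal effect of the metabolite and configurable balanced or
  directional instrument pleiotropy, binarised by thresholding at the
  case fraction;
* a strict two-sample design: exposure and outcome summary statistics
  never share individuals.

Default parameter values reproduce the study conditions of a glycine-
scale metabolite GWAS: a dominant locus with within-sex standardized
effects 0.69 (women) / 0.23 (men) at EAF 0.313, a polygenic background
bringing the common-variant variance explained to roughly 25% in women
and 11% in men, raw-scale SDs 0.321 / 0.195 around a unit geometric
mean, and a causal exposure-outcome effect of 0.2 on the liability
scale for estimator-recovery experiments.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import z_to_p
from .loci import LDReference
from .mr import InstrumentSet
from .sumstats import StudySumstats

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_metabolite",
    "simulate_outcome",
    "simulate_summary_instruments",
    "simulate_two_sample_study",
    "cohort_gwas",
    "prep_phenotype",
    "bp_medication_adjust",
]

_DOMINANT_EAF = 0.313
_DOMINANT_BETA_F = 0.69
_DOMINANT_BETA_M = 0.23
_BACKGROUND_BETA_F = 0.070
_BACKGROUND_BETA_M = 0.095
_RAW_SD_F = 0.321
_RAW_SD_M = 0.195


@dataclass
class SimConfig:
    """Generative parameters for one synthetic study.

    ``beta_f`` / ``beta_m`` are per-allele effects on the latent
    metabolite in within-sex SD units; when left ``None`` a default
    architecture is used (one dominant sex-dimorphic locus plus an equal-
    effect background, see module docstring).  When ``h2`` is ``None``
    the betas are taken literally and environmental noise tops the
    within-sex variance up to 1 (an error if the genetic variance already
    exceeds 1); when ``h2`` is given, the beta vectors are rescaled per
    sex so the genetic fraction of within-sex variance equals ``h2``
    exactly.
    """

    seed: int = 0
    n_exposure_sample: int = 20_000
    n_outcome_sample: int = 20_000
    m_variants: int = 24
    maf_range: tuple = (0.1, 0.5)
    ld_blocks: list | None = None          # [(size, rho), ...]
    beta_f: Sequence | None = None
    beta_m: Sequence | None = None
    h2: float | None = None
    theta: float = 0.2
    pleiotropy_mode: str = "none"          # none | balanced | directional
    tau2: float = 0.0
    mu_alpha: float = 0.0
    pleiotropy_fraction: float = 1.0
    outcome_type: str = "quantitative"     # quantitative | binary
    case_fraction: float = 0.1
    female_fraction: float = 0.5
    raw_sd_f: float = _RAW_SD_F
    raw_sd_m: float = _RAW_SD_M
    raw_mean: float = 1.0

    def __post_init__(self):
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.h2 is not None and not (0 <= self.h2 < 1):
            raise ValueError("h2 must lie in [0, 1)")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.ld_blocks is not None:
            if sum(s for s, _ in self.ld_blocks) != self.m_variants:
                raise ValueError("ld_blocks sizes must sum to m_variants")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")

    def blocks(self) -> list:
        if self.ld_blocks is None:
            return [(1, 0.0)] * self.m_variants
        return list(self.ld_blocks)

    def effects(self) -> tuple:
        """(beta_f, beta_m) arrays, applying the default architecture."""
        if self.beta_f is not None and self.beta_m is not None:
            bf = np.asarray(self.beta_f, dtype=float)
            bm = np.asarray(self.beta_m, dtype=float)
        else:
            bf = np.full(self.m_variants, _BACKGROUND_BETA_F)
            bm = np.full(self.m_variants, _BACKGROUND_BETA_M)
            bf[0], bm[0] = _DOMINANT_BETA_F, _DOMINANT_BETA_M
        if len(bf) != self.m_variants or len(bm) != self.m_variants:
            raise ValueError("effect vectors must have length m_variants")
        return bf, bm

    def mafs(self, rng: np.random.Generator) -> np.ndarray:
        maf = rng.uniform(*self.maf_range, size=self.m_variants)
        if self.beta_f is None:
            maf[0] = _DOMINANT_EAF
        return maf

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=2, default=list)


def _dprime_matrix(haps: np.ndarray) -> np.ndarray:
    """|D'| between all variant pairs from phased haplotypes (0/1)."""
    nh, m = haps.shape
    haps = haps.astype(np.float64)  # BLAS path for the pairwise product
    p = haps.mean(axis=0)
    pab = haps.T @ haps / nh
    D = pab - np.outer(p, p)
    dmax_pos = np.minimum(np.outer(p, 1 - p), np.outer(1 - p, p))
    dmax_neg = np.minimum(np.outer(p, p), np.outer(1 - p, 1 - p))
    dmax = np.where(D >= 0, dmax_pos, dmax_neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        dp = np.abs(D) / dmax
    dp[~np.isfinite(dp)] = 0.0
    np.fill_diagonal(dp, 1.0)
    return np.clip(dp, 0.0, 1.0)


def simulate_genotypes(config: SimConfig, n: int | None = None,
                       rng: np.random.Generator | None = None,
                       mafs: np.ndarray | None = None,
                       with_ld: bool = True):
    """Simulate diploid dosages and the matching LD reference.

    Each haplotype allele within a block shares a latent standard normal
    with equicorrelation ``rho``, thresholded at the MAF quantile; the
    two haplotypes of an individual are independent, blocks are
    independent.  Returns ``(dosages, LDReference)`` with the reference
    computed from the generated sample (dosage correlations, haplotype
    |D'|, sample EAFs).  Deterministic under ``config.seed`` when ``rng``
    is not supplied.  ``with_ld=False`` skips the (quadratic-in-m) LD
    reference and returns ``(dosages, None)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = n or config.n_exposure_sample
    if mafs is None:
        mafs = config.mafs(rng)
    haps = []
    j0 = 0
    for size, rho in config.blocks():
        t = stats.norm.ppf(mafs[j0:j0 + size])
        for _ in range(2):
            shared = rng.standard_normal((n, 1))
            eps = rng.standard_normal((n, size))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
            haps.append((z < t).astype(np.int8))
        j0 += size
    h1 = np.concatenate(haps[0::2], axis=1)
    h2 = np.concatenate(haps[1::2], axis=1)
    dosages = (h1 + h2).astype(float)
    if not with_ld:
        return dosages, None

    with np.errstate(invalid="ignore"):
        R = np.corrcoef(dosages, rowvar=False)
    R = np.atleast_2d(R)
    R[~np.isfinite(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    eaf = dosages.mean(axis=0) / 2.0
    dprime = _dprime_matrix(np.concatenate([h1, h2], axis=0))
    ids = [f"rs{j + 1}" for j in range(config.m_variants)]
    side = pd.DataFrame({"SNP": ids, "CHR": "1",
                         "POS": [100_000 * (j + 1) for j in range(config.m_variants)],
                         "EA": "A", "OA": "G", "EAF": eaf})
    ld = LDReference(variant_ids=ids, R=R, eaf=eaf, n_ref=n, dprime=dprime,
                     sidecar=side)
    return dosages, ld


def simulate_metabolite(dosages: np.ndarray, sex: np.ndarray,
                        config: SimConfig,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate raw (positive, log-normal) metabolite values.

    The latent trait is ``X beta_sex + noise``; see :class:`SimConfig`
    for how the noise scale is set.  The latent is then standardized
    within sex and mapped through a log-normal with the configured
    per-sex raw mean and SD, so the pipeline's log / winsorise / z-score
    preparation is exercised on realistic raw values.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    bf, bm = config.effects()
    sex = np.asarray(sex)
    latent = np.empty(len(dosages))
    for label, beta in (("F", bf), ("M", bm)):
        mask = sex == label
        if not mask.any():
            continue
        g = dosages[mask] @ beta
        gvar = float(np.var(g))
        if config.h2 is None:
            if gvar >= 1.0:
                raise ValueError(
                    f"genetic variance {gvar:.3f} >= 1 in stratum {label}: "
                    "within-sex SD-unit effects are infeasible")
            noise_var = 1.0 - gvar
        else:
            if config.h2 == 0:
                g = np.zeros(mask.sum())
                noise_var = 1.0
            else:
                if gvar == 0:
                    raise ValueError("h2 > 0 requires nonzero genetic effects")
                g = g * np.sqrt(config.h2 / gvar)
                noise_var = 1.0 - config.h2
        latent[mask] = g + rng.normal(0.0, np.sqrt(noise_var), mask.sum())

    raw = np.empty_like(latent)
    for label, sd in (("F", config.raw_sd_f), ("M", config.raw_sd_m)):
        mask = sex == label
        if not mask.any():
            continue
        z = (latent[mask] - latent[mask].mean()) / latent[mask].std()
        # log-normal with target arithmetic mean and SD
        sigma2 = np.log1p((sd / config.raw_mean) ** 2)
        mu = np.log(config.raw_mean) - sigma2 / 2.0
        raw[mask] = np.exp(mu + np.sqrt(sigma2) * z)
    return raw


def simulate_outcome(config: SimConfig,
                     dosages: np.ndarray | None = None,
                     exposure: np.ndarray | None = None,
                     rng: np.random.Generator | None = None):
    """Simulate the outcome from a liability model.

    liability = theta * standardized(exposure) + sum_j alpha_j dosage_j
    + N(0, 1), with direct effects ``alpha`` drawn per
    ``pleiotropy_mode`` on the fraction ``pleiotropy_fraction`` of
    variants.  Binary outcomes threshold the liability at its
    ``1 - case_fraction`` quantile.  Returns ``(outcome, alpha)``.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n = len(exposure) if exposure is not None else len(dosages)
    liability = rng.standard_normal(n)
    if exposure is not None and config.theta != 0:
        x = np.asarray(exposure, dtype=float)
        liability = liability + config.theta * (x - x.mean()) / x.std()
    alpha = np.zeros(config.m_variants)
    if config.pleiotropy_mode != "none":
        k_pleio = int(round(config.pleiotropy_fraction * config.m_variants))
        which = rng.choice(config.m_variants, size=k_pleio, replace=False)
        mean = config.mu_alpha if config.pleiotropy_mode == "directional" else 0.0
        alpha[which] = rng.normal(mean, np.sqrt(config.tau2), k_pleio)
    if dosages is not None and alpha.any():
        liability = liability + dosages @ alpha
    if config.outcome_type == "binary":
        cut = np.quantile(liability, 1.0 - config.case_fraction)
        return (liability > cut).astype(int), alpha
    return liability, alpha


def prep_phenotype(raw: np.ndarray) -> np.ndarray:
    """Standard metabolite preparation: natural log, winsorise at 5 SDs
    (SD computed before clipping), then z-standardize."""
    raw = np.asarray(raw, dtype=float)
    if (raw <= 0).any():
        raise ValueError("raw metabolite values must be positive")
    y = np.log(raw)
    mu, sd = y.mean(), y.std()
    y = np.clip(y, mu - 5 * sd, mu + 5 * sd)
    return (y - y.mean()) / y.std()


def bp_medication_adjust(sbp: np.ndarray, dbp: np.ndarray,
                         on_treatment: np.ndarray):
    """Add the standard treatment offsets (+15 mmHg systolic, +10 mmHg
    diastolic) to measured pressures of treated individuals.

    Operates on raw measurements only; callers must not re-apply it.
    """
    sbp = np.asarray(sbp, dtype=float).copy()
    dbp = np.asarray(dbp, dtype=float).copy()
    t = np.asarray(on_treatment, dtype=bool)
    sbp[t] += 15.0
    dbp[t] += 10.0
    return sbp, dbp


def _logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 50):
    """Newton-Raphson logistic regression; returns (coef, se)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wdiag = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * wdiag[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(hess)
    return beta, np.sqrt(np.diag(cov))


def cohort_gwas(dosages: np.ndarray, phenotype: np.ndarray,
                covariates: np.ndarray | None = None,
                binary: bool = False,
                study_id: str = "sim", trait: str = "trait",
                variant_ids: Sequence[str] | None = None,
                positions: Sequence[int] | None = None) -> StudySumstats:
    """Per-variant marginal association scan.

    Quantitative phenotypes use least squares (phenotype and dosages
    residualised on the covariates first, so this is the standard
    covariate-adjusted marginal regression); binary phenotypes use a
    per-variant logistic fit producing effects on the log-odds scale.
    Monomorphic variants are emitted with NA effects and noted in
    ``result.report``.
    """
    from .sumstats import ReadReport  # local import to avoid cycle at import time

    dosages = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = dosages.shape
    eaf = dosages.mean(axis=0) / 2.0
    mono = dosages.std(axis=0) == 0
    report = ReadReport(n_parsed=m, n_rejected=0)
    for j in np.flatnonzero(mono):
        report.messages.append(f"variant {j}: monomorphic, effects set to NA")

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    if binary:
        C = (np.ones((n, 1)) if covariates is None
             else np.column_stack([np.ones(n), covariates]))
        for j in range(m):
            if mono[j]:
                continue
            X = np.column_stack([C, dosages[:, j]])
            coef, ses = _logistic_fit(X, y)
            beta[j], se[j] = coef[-1], ses[-1]
    else:
        if covariates is not None:
            C = np.column_stack([np.ones(n), covariates])
            H = np.linalg.lstsq(C, np.column_stack([y[:, None], dosages]),
                                rcond=None)[0]
            fitted = C @ H
            y = y - fitted[:, 0]
            X = dosages - fitted[:, 1:]
            q = C.shape[1]
        else:
            y = y - y.mean()
            X = dosages - dosages.mean(axis=0)
            q = 1
        xx = np.sum(X * X, axis=0)
        ok = ~mono
        xy = X.T @ y
        beta[ok] = xy[ok] / xx[ok]
        dof = n - q - 1
        rss = np.sum(y * y) - beta[ok] * xy[ok]  # per-variant residual SS
        sigma2 = rss / dof
        se[ok] = np.sqrt(sigma2 / xx[ok])

    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = np.where(np.isfinite(z), z_to_p(np.where(np.isfinite(z), z, 0.0)), np.nan)
    ids = list(variant_ids) if variant_ids is not None else [f"rs{j+1}" for j in range(m)]
    pos = list(positions) if positions is not None else [100_000 * (j + 1) for j in range(m)]
    df = pd.DataFrame({
        "snp": ids, "chrom": "1", "pos": pos, "ea": "A", "oa": "G",
        "eaf": eaf, "beta": beta, "se": se, "z": z, "p": p,
        "n": float(n), "info": 1.0, "hwe_p": np.nan,
    })
    return StudySumstats(study_id=study_id, trait=trait, df=df,
                         n_total=n, report=report)


def simulate_summary_instruments(config: SimConfig,
                                 rng: np.random.Generator | None = None,
                                 gamma_range: tuple = (0.08, 0.5)):
    """Directly simulate two-sample instrument summary statistics.

    Works on the summary level (no individual-level data): true
    instrument-exposure effects ``gamma_j`` are drawn uniformly from
    ``gamma_range`` (exposure SD per allele), standard errors follow the
    large-sample formula ``1 / sqrt(n * 2 p (1 - p))`` for a
    standardized trait, and observed effects add independent normal
    noise in the exposure and outcome samples (the two-sample design).

    The default ``gamma_range`` reflects a discovery-filtered instrument
    set: at the default exposure sample size a variant only reaches
    genome-wide significance when its per-allele effect exceeds roughly
    0.06-0.09 SD (5.45 standard errors), and metabolite instruments run
    up to ~0.5 SD per allele at the strongest locus.
    Outcome effects are ``theta * gamma_j + alpha_j`` with direct
    effects ``alpha`` per the configured pleiotropy mode.

    Returns ``(InstrumentSet, truth)`` where ``truth`` records the drawn
    generative quantities.
    """
    rng = rng or np.random.default_rng(config.seed)
    k = config.m_variants
    maf = rng.uniform(*config.maf_range, size=k)
    v = 2.0 * maf * (1.0 - maf)
    gamma = rng.uniform(*gamma_range, size=k)
    se_x = 1.0 / np.sqrt(config.n_exposure_sample * v)
    se_y = 1.0 / np.sqrt(config.n_outcome_sample * v)
    alpha = np.zeros(k)
    if config.pleiotropy_mode != "none":
        k_pleio = int(round(config.pleiotropy_fraction * k))
        which = rng.choice(k, size=k_pleio, replace=False)
        mean = config.mu_alpha if config.pleiotropy_mode == "directional" else 0.0
        alpha[which] = rng.normal(mean, np.sqrt(config.tau2), k_pleio)
    gamma_hat = gamma + se_x * rng.standard_normal(k)
    Gamma_hat = config.theta * gamma + alpha + se_y * rng.standard_normal(k)
    inst = InstrumentSet(gamma_x=gamma_hat, se_x=se_x, Gamma_y=Gamma_hat,
                         se_y=se_y, snp=[f"rs{j+1}" for j in range(k)])
    truth = {"theta": config.theta, "gamma": gamma, "alpha": alpha,
             "maf": maf}
    return inst, truth


def simulate_mediation_instruments(config: SimConfig,
                                   rng: np.random.Generator | None = None,
                                   theta_direct: float = -0.03,
                                   theta_mediator: float = 0.2,
                                   exposure_to_mediator: float = -0.5,
                                   direct_mediator_sd: float = 0.05,
                                   n_mediator_sample: int = 150_000,
                                   gamma_range: tuple = (0.08, 0.5)):
    """Summary-level mediation scenario for multivariable MR.

    The exposure affects a mediator (effect ``exposure_to_mediator`` per
    exposure SD), each instrument additionally has an independent direct
    effect on the mediator (SD ``direct_mediator_sd``, which is what
    makes the two exposure columns non-collinear), and the outcome
    liability receives a direct exposure effect ``theta_direct`` plus a
    mediator effect ``theta_mediator``.  The univariable
    exposure-outcome effect is therefore ``theta_direct +
    theta_mediator * exposure_to_mediator`` while the
    mediator-adjusted multivariable coefficient targets
    ``theta_direct``.

    Returns ``(InstrumentSet with exposure columns [exposure,
    mediator], truth dict)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    k = config.m_variants
    maf = rng.uniform(*config.maf_range, size=k)
    v = 2.0 * maf * (1.0 - maf)
    gamma = rng.uniform(*gamma_range, size=k)
    d = rng.normal(0.0, direct_mediator_sd, k)
    gamma_med = d + exposure_to_mediator * gamma
    Gamma_out = theta_direct * gamma + theta_mediator * gamma_med

    se_x = 1.0 / np.sqrt(config.n_exposure_sample * v)
    se_med = 1.0 / np.sqrt(n_mediator_sample * v)
    se_y = 1.0 / np.sqrt(config.n_outcome_sample * v)
    gamma_hat = gamma + se_x * rng.standard_normal(k)
    med_hat = gamma_med + se_med * rng.standard_normal(k)
    out_hat = Gamma_out + se_y * rng.standard_normal(k)
    inst = InstrumentSet(
        gamma_x=gamma_hat, se_x=se_x, Gamma_y=out_hat, se_y=se_y,
        snp=[f"rs{j+1}" for j in range(k)],
        exposures=np.column_stack([gamma_hat, med_hat]),
        exposure_names=["exposure", "mediator"])
    truth = {"theta_direct": theta_direct, "theta_mediator": theta_mediator,
             "exposure_to_mediator": exposure_to_mediator,
             "theta_total": theta_direct + theta_mediator * exposure_to_mediator,
             "gamma": gamma, "gamma_mediator": gamma_med}
    return inst, truth


def simulate_two_sample_study(config: SimConfig):
    """Full individual-level two-sample study.

    Generates non-overlapping exposure and outcome samples from the same
    population, runs the per-variant GWAS in each, and returns a dict
    with the exposure and outcome :class:`StudySumstats`, the exposure-
    sample :class:`LDReference`, sex labels, raw phenotype and ground
    truth.  Bit-reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mafs = config.mafs(rng)

    dos_x, ld = simulate_genotypes(config, n=config.n_exposure_sample,
                                   rng=rng, mafs=mafs)
    sex_x = np.where(rng.random(config.n_exposure_sample) < config.female_fraction,
                     "F", "M")
    raw = simulate_metabolite(dos_x, sex_x, config, rng=rng)
    pheno = prep_phenotype(raw)
    gwas_x = cohort_gwas(dos_x, pheno, study_id="exposure",
                         trait="metabolite")

    dos_y, _ = simulate_genotypes(config, n=config.n_outcome_sample,
                                  rng=rng, mafs=mafs)
    sex_y = np.where(rng.random(config.n_outcome_sample) < config.female_fraction,
                     "F", "M")
    raw_y = simulate_metabolite(dos_y, sex_y, config, rng=rng)
    exposure_y = prep_phenotype(raw_y)
    outcome, alpha = simulate_outcome(config, dosages=dos_y,
                                      exposure=exposure_y, rng=rng)
    gwas_y = cohort_gwas(dos_y, outcome,
                         binary=(config.outcome_type == "binary"),
                         study_id="outcome", trait="disease")
    truth = {"theta": config.theta, "alpha": alpha, "maf": mafs,
             "beta_f": config.effects()[0], "beta_m": config.effects()[1]}
    return {"exposure": gwas_x, "outcome": gwas_y, "ld": ld,
            "sex_exposure": sex_x, "raw_exposure": raw,
            "config": config, "truth": truth}
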