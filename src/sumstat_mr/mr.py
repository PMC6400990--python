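"""Two-sample Mendelian randomization from harmonized summary statistics.

The data container is an :class:`InstrumentSet`: per-variant effects of
the instruments on the exposure (gamma, se_x) and on the outcome
(Gamma, se_y), harmonized to a common effect-allele orientation.  The
model object :class:`MendelianRandomization` wraps one instrument set;
``fit(method=...)`` returns an :class:`MRResults` carrying the causal
estimate, its uncertainty and diagnostics, with ``summary()``,
odds-ratio and rescaling views, in the style of statsmodels model /
results pairs.

Estimators
----------
wald
    Single-instrument ratio ``Gamma / gamma`` with first-order
    (delta-method) SE ``|se_y / gamma|``.
ivw
    Inverse-variance-weighted combination of the per-instrument ratios;
    identical to weighted regression of Gamma on gamma through the
    origin with weights ``1 / se_y^2``.  Fixed-effect SE by default
    (``random_effect=True`` inflates by the multiplicative residual
    scale); heterogeneity reported separately as Cochran's Q.
egger
    Weighted regression with a free intercept (instruments oriented so
    gamma >= 0); the intercept estimates average directional pleiotropy
    and its two-sided p is the pleiotropy test.  Requires the InSIDE
    assumption.
wmedian / pwmedian
    Weighted median of the per-instrument ratios (consistent when at
    least half the weight comes from valid instruments), and its
    penalized variant which down-weights instruments with outlying
    heterogeneity contributions.  SEs by seeded parametric bootstrap.
mvmr
    Multivariable MR: weighted regression of the outcome effects on
    several exposures' effect columns, no intercept; each coefficient is
    that exposure's direct effect adjusted for the others.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import z_to_log10p, z_to_p

__all__ = [
    "InstrumentSet",
    "MRResults",
    "MVMRResults",
    "MendelianRandomization",
    "MultivariableMR",
    "wald_ratio",
    "mr_ivw",
    "mr_egger",
    "mr_weighted_median",
    "mr_penalized_weighted_median",
    "mr_multivariable",
    "scale_and_transform",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class InstrumentSet:
    """Harmonized per-variant exposure and outcome effects.

    ``gamma_x`` are instrument-exposure effects (exposure SD per allele
    unless stated otherwise), ``Gamma_y`` instrument-outcome effects
    (log-odds or outcome SD per allele).  ``exposures`` optionally holds
    a (k, p) matrix of effect columns for multivariable MR, with
    ``exposure_names`` naming the columns.
    """

    gamma_x: np.ndarray
    se_x: np.ndarray
    Gamma_y: np.ndarray
    se_y: np.ndarray
    snp: list | None = None
    exposures: np.ndarray | None = None
    exposure_names: list | None = None

    def __post_init__(self):
        for name in ("gamma_x", "se_x", "Gamma_y", "se_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.gamma_x)
        if not (len(self.se_x) == len(self.Gamma_y) == len(self.se_y) == k):
            raise ValueError("instrument arrays must share a length")
        if (self.se_x <= 0).any() or (self.se_y <= 0).any():
            raise ValueError("standard errors must be positive")
        if self.exposures is not None:
            self.exposures = np.atleast_2d(np.asarray(self.exposures, dtype=float))
            if self.exposures.shape[0] != k:
                raise ValueError("exposure matrix row count mismatch")
            if self.exposure_names is None:
                self.exposure_names = [f"x{j}" for j in range(self.exposures.shape[1])]

    def __len__(self) -> int:
        return len(self.gamma_x)

    @classmethod
    def from_harmonized(cls, df: pd.DataFrame) -> "InstrumentSet":
        """Build from a :func:`sumstat_mr.sumstats.harmonize_tables` frame."""
        return cls(gamma_x=df["gamma_x"].to_numpy(),
                   se_x=df["se_x"].to_numpy(),
                   Gamma_y=df["Gamma_y"].to_numpy(),
                   se_y=df["se_y"].to_numpy(),
                   snp=list(df["snp"]) if "snp" in df else None)

    def oriented(self) -> "InstrumentSet":
        """Copy with every instrument flipped so gamma_x >= 0 (the
        orientation MR-Egger's intercept needs)."""
        sign = np.where(self.gamma_x < 0, -1.0, 1.0)
        return dataclasses.replace(
            self, gamma_x=self.gamma_x * sign, Gamma_y=self.Gamma_y * sign,
            exposures=None if self.exposures is None
            else self.exposures * sign[:, None],
        )

    def ratios(self) -> np.ndarray:
        return self.Gamma_y / self.gamma_x

    def ratio_weights(self) -> np.ndarray:
        """Leading-order inverse-variance weights of the per-instrument
        ratios, ``gamma^2 / se_y^2``."""
        return self.gamma_x**2 / self.se_y**2


@dataclass
class MRResults:
    """Causal-effect estimate with uncertainty and diagnostics."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    log10_p: float = np.nan
    n_instruments: int = 0
    q: float = np.nan
    q_df: int = 0
    q_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_p: float = np.nan
    n_boot: int = 0
    seed: int | None = None

    def odds_ratio(self):
        """(OR, CI low, CI high) per exposure SD — exp-transform of the
        estimate; valid when Gamma_y is on the log-odds scale."""
        return (float(np.exp(self.theta)), float(np.exp(self.ci_low)),
                float(np.exp(self.ci_high)))

    def rescaled(self, factor: float) -> "MRResults":
        """Multiply the estimate and its uncertainty by ``factor``
        (e.g. an exposure SD to move from raw-unit to per-SD effects)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return dataclasses.replace(
            self, theta=self.theta * factor, se=self.se * factor,
            ci_low=self.ci_low * factor, ci_high=self.ci_high * factor)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def summary(self) -> str:
        lines = [
            f"Two-sample MR ({self.method}), k = {self.n_instruments} instruments",
            f"  theta = {self.theta:+.4f}  se = {self.se:.4f}  "
            f"95% CI [{self.ci_low:+.4f}, {self.ci_high:+.4f}]  p = {self.p:.3g}",
        ]
        orv, lo, hi = self.odds_ratio()
        lines.append(f"  OR per exposure SD = {orv:.3f} [{lo:.3f}, {hi:.3f}]"
                     " (log-odds outcome scale)")
        if np.isfinite(self.q):
            lines.append(f"  Cochran Q = {self.q:.3f} (df {self.q_df}), "
                         f"p = {self.q_p:.3g}")
        if np.isfinite(self.egger_intercept):
            lines.append(
                f"  Egger intercept = {self.egger_intercept:+.4f} "
                f"(se {self.egger_intercept_se:.4f}, "
                f"p = {self.egger_intercept_p:.3g})")
        if self.n_boot:
            lines.append(f"  bootstrap: {self.n_boot} draws, seed {self.seed}")
        return "\n".join(lines)


def _finalize(method, theta, se, k, **extra) -> MRResults:
    z = theta / se if se > 0 else np.inf * np.sign(theta)
    return MRResults(
        method=method, theta=float(theta), se=float(se),
        ci_low=float(theta - _Z95 * se), ci_high=float(theta + _Z95 * se),
        p=float(z_to_p(z)), log10_p=float(z_to_log10p(z)),
        n_instruments=k, **extra)


def wald_ratio(gamma_x: float, se_x: float, Gamma_y: float,
               se_y: float) -> MRResults:
    """Single-instrument causal estimate (first-order delta SE)."""
    if gamma_x == 0:
        raise ValueError("instrument-exposure effect is zero")
    theta = Gamma_y / gamma_x
    se = abs(se_y / gamma_x)
    return _finalize("wald", theta, se, 1)


def _ratio_q(inst: InstrumentSet, theta: float):
    w = inst.ratio_weights()
    q = float(np.sum(w * (inst.ratios() - theta) ** 2))
    df = len(inst) - 1
    return q, df, float(stats.chi2.sf(q, df)) if df > 0 else np.nan


def mr_ivw(inst: InstrumentSet, random_effect: bool = False) -> MRResults:
    """Inverse-variance-weighted estimate.

    Fixed-effect SE by default; with ``random_effect=True`` the SE is
    inflated by the multiplicative residual scale (never deflated).
    """
    if len(inst) == 0:
        raise ValueError("empty instrument set")
    if len(inst) == 1:
        return mr_ivw_single(inst)
    gx, gy, w = inst.gamma_x, inst.Gamma_y, 1.0 / inst.se_y**2
    denom = np.sum(w * gx**2)
    theta = np.sum(w * gx * gy) / denom
    se = denom**-0.5
    q, q_df, q_p = _ratio_q(inst, theta)
    if random_effect and q_df > 0:
        se *= max(1.0, np.sqrt(q / q_df))
    return _finalize("ivw", theta, se, len(inst), q=q, q_df=q_df, q_p=q_p)


def mr_ivw_single(inst: InstrumentSet) -> MRResults:
    res = wald_ratio(inst.gamma_x[0], inst.se_x[0], inst.Gamma_y[0],
                     inst.se_y[0])
    return dataclasses.replace(res, method="ivw")


def mr_egger(inst: InstrumentSet) -> MRResults:
    """MR-Egger regression: weighted fit of Gamma on gamma with a free
    intercept; the intercept is the directional-pleiotropy estimate."""
    if len(inst) < 3:
        raise ValueError("MR-Egger needs at least three instruments")
    inst = inst.oriented()
    x, y, w = inst.gamma_x, inst.Gamma_y, 1.0 / inst.se_y**2
    X = np.column_stack([np.ones(len(x)), x])
    xtwx = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(xtwx)
    coef = cov @ (X.T @ (w * y))
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    q_df = len(x) - 2
    res = _finalize("egger", slope, se_slope, len(inst),
                    q=q, q_df=q_df,
                    q_p=float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan)
    return dataclasses.replace(
        res, egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_p=float(z_to_p(intercept / se_int)))


def _weighted_median_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by linear interpolation of the cumulative
    weight midpoints across the sorted ratios (2-D inputs)."""
    order = np.argsort(theta, axis=1)
    th = np.take_along_axis(theta, order, axis=1)
    ww = np.take_along_axis(w, order, axis=1)
    ww = ww / ww.sum(axis=1, keepdims=True)
    s = np.cumsum(ww, axis=1) - ww / 2.0
    nb, k = th.shape
    idx = np.sum(s < 0.5, axis=1)  # first position with s >= 0.5
    out = np.empty(nb)
    at_low = idx == 0
    at_high = idx == k
    out[at_low] = th[at_low, 0]
    out[at_high] = th[at_high, -1]
    mid = ~(at_low | at_high)
    i = idx[mid]
    rows = np.flatnonzero(mid)
    s_lo, s_hi = s[rows, i - 1], s[rows, i]
    t_lo, t_hi = th[rows, i - 1], th[rows, i]
    out[mid] = t_lo + (t_hi - t_lo) * (0.5 - s_lo) / (s_hi - s_lo)
    return out


def weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median of ratios ``theta`` with weights ``w`` (the
    interpolated definition used throughout this module)."""
    return float(_weighted_median_rows(np.asarray(theta, dtype=float)[None, :],
                                       np.asarray(w, dtype=float)[None, :])[0])


def _penalized_weights(theta: np.ndarray, w: np.ndarray,
                       penalty: float) -> np.ndarray:
    """Down-weight instruments with outlying one-df heterogeneity
    contributions around the unpenalized weighted median."""
    wm = _weighted_median_rows(theta, w) if theta.ndim == 2 else None
    if theta.ndim == 1:
        theta = theta[None, :]
        w = w[None, :]
        wm = _weighted_median_rows(theta, w)
    Q = w * (theta - wm[:, None]) ** 2
    qp = stats.chi2.sf(Q, 1)
    return w * np.minimum(1.0, penalty * qp)


def _median_bootstrap(inst: InstrumentSet, n_boot: int, seed,
                      weights: np.ndarray) -> float:
    """Parametric bootstrap SE of a weighted-median estimate: resample
    the instrument effects from their observed sampling distributions,
    recompute the ratios, and re-take the weighted median with the
    observed ``weights`` held fixed (the convention of the estimator's
    originating implementation)."""
    rng = np.random.default_rng(seed)
    gx = inst.gamma_x + inst.se_x * rng.standard_normal((n_boot, len(inst)))
    gy = inst.Gamma_y + inst.se_y * rng.standard_normal((n_boot, len(inst)))
    theta = gy / gx
    w = np.broadcast_to(weights, theta.shape)
    return float(np.std(_weighted_median_rows(theta, w)))


def mr_weighted_median(inst: InstrumentSet, n_boot: int = 5000,
                       seed: int | None = None) -> MRResults:
    """Weighted median of the per-instrument ratios, with a seeded
    parametric-bootstrap SE."""
    if len(inst) < 3:
        raise ValueError("weighted median needs at least three instruments")
    w = inst.ratio_weights()
    theta = weighted_median(inst.ratios(), w)
    se = _median_bootstrap(inst, n_boot, seed, weights=w)
    q, q_df, q_p = _ratio_q(inst, theta)
    return _finalize("wmedian", theta, se, len(inst), q=q, q_df=q_df,
                     q_p=q_p, n_boot=n_boot, seed=seed)


def mr_penalized_weighted_median(inst: InstrumentSet, penalty: float = 20.0,
                                 n_boot: int = 5000,
                                 seed: int | None = None) -> MRResults:
    """Weighted median with heterogeneity-penalized weights."""
    if len(inst) < 3:
        raise ValueError("weighted median needs at least three instruments")
    ratios = inst.ratios()
    w = inst.ratio_weights()
    w_pen = _penalized_weights(ratios, w, penalty)[0]
    theta = weighted_median(ratios, w_pen)
    se = _median_bootstrap(inst, n_boot, seed, weights=w_pen)
    q, q_df, q_p = _ratio_q(inst, theta)
    return _finalize("pwmedian", theta, se, len(inst), q=q, q_df=q_df,
                     q_p=q_p, n_boot=n_boot, seed=seed)


@dataclass
class MVMRResults:
    """Per-exposure direct-effect estimates from multivariable MR."""

    estimates: list  # list[MRResults], one per retained exposure
    exposure_names: list
    dropped: list = field(default_factory=list)

    def __getitem__(self, name: str) -> MRResults:
        return self.estimates[self.exposure_names.index(name)]

    def summary(self) -> str:
        lines = [f"Multivariable MR ({len(self.exposure_names)} exposures)"]
        for name, est in zip(self.exposure_names, self.estimates):
            lines.append(f"  {name}: theta = {est.theta:+.4f} "
                         f"(se {est.se:.4f}, p = {est.p:.3g})")
        if self.dropped:
            lines.append(f"  dropped zero columns: {self.dropped}")
        return "\n".join(lines)


def mr_multivariable(inst: InstrumentSet) -> MVMRResults:
    """Weighted multivariable regression of outcome effects on the
    exposure-effect columns (no intercept, weights 1/se_y^2).

    Exposure columns that are identically zero carry no information and
    are dropped (reported in ``dropped``); genuinely collinear columns
    raise ``ValueError``.
    """
    if inst.exposures is None:
        raise ValueError("instrument set has no exposure matrix")
    G = inst.exposures
    names = list(inst.exposure_names)
    zero = np.all(G == 0, axis=0)
    dropped = [n for n, z in zip(names, zero) if z]
    G = G[:, ~zero]
    names = [n for n, z in zip(names, zero) if not z]
    k, p = G.shape
    if k < p + 1:
        raise ValueError("need more instruments than exposures")
    w = 1.0 / inst.se_y**2
    gtwg = G.T @ (w[:, None] * G)
    if np.linalg.cond(gtwg) > 1e8:
        raise ValueError("exposure-effect columns are collinear")
    cov = np.linalg.inv(gtwg)
    coef = cov @ (G.T @ (w * inst.Gamma_y))
    ses = np.sqrt(np.diag(cov))
    ests = [dataclasses.replace(_finalize("mvmr", b, s, k))
            for b, s in zip(coef, ses)]
    return MVMRResults(estimates=ests, exposure_names=names, dropped=dropped)


def scale_and_transform(estimate: MRResults, exposure_sd: float,
                        as_odds_ratio: bool = False):
    """Convert an estimate fitted with raw-unit instrument-exposure
    effects to a per-exposure-SD effect (multiply by ``exposure_sd``);
    optionally return the odds-ratio view.

    Dividing gamma by the SD before estimation and multiplying theta by
    the SD after are the same linear rescaling, so both routes agree.
    """
    if exposure_sd <= 0:
        raise ValueError("exposure SD must be positive")
    out = estimate.rescaled(exposure_sd)
    if as_odds_ratio:
        return out.odds_ratio()
    return out


class MendelianRandomization:
    """Model object for univariable two-sample MR on one instrument set."""

    METHODS = ("wald", "ivw", "egger", "wmedian", "pwmedian")

    def __init__(self, instruments: InstrumentSet):
        self.instruments = instruments

    @classmethod
    def from_harmonized(cls, df: pd.DataFrame) -> "MendelianRandomization":
        return cls(InstrumentSet.from_harmonized(df))

    def fit(self, method: str = "ivw", n_boot: int = 5000,
            seed: int | None = None, penalty: float = 20.0,
            random_effect: bool = False) -> MRResults:
        inst = self.instruments
        if method == "wald":
            if len(inst) != 1:
                raise ValueError("wald requires exactly one instrument")
            return wald_ratio(inst.gamma_x[0], inst.se_x[0],
                              inst.Gamma_y[0], inst.se_y[0])
        if method == "ivw":
            return mr_ivw(inst, random_effect=random_effect)
        if method == "egger":
            return mr_egger(inst)
        if method == "wmedian":
            return mr_weighted_median(inst, n_boot=n_boot, seed=seed)
        if method == "pwmedian":
            return mr_penalized_weighted_median(inst, penalty=penalty,
                                                n_boot=n_boot, seed=seed)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, methods: Sequence[str] = ("ivw", "egger", "wmedian",
                                                "pwmedian"),
                **kwargs) -> pd.DataFrame:
        """Fit several estimators; one row per method."""
        rows = [self.fit(m, **kwargs).to_dict() for m in methods]
        return pd.DataFrame(rows)

    def plot_scatter(self, results: Sequence[MRResults] = (), ax=None):
        """Instrument-effect scatter (gamma vs Gamma) with +-1.96 SE bars
        and fitted slopes."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        inst = self.instruments.oriented()
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(inst.gamma_x, inst.Gamma_y, xerr=_Z95 * inst.se_x,
                    yerr=_Z95 * inst.se_y, fmt="o", ms=4, lw=0.8,
                    color="0.3", ecolor="0.7")
        xs = np.linspace(0, inst.gamma_x.max() * 1.05, 50)
        for res in results:
            icpt = res.egger_intercept if np.isfinite(res.egger_intercept) else 0.0
            ax.plot(xs, icpt + res.theta * xs, label=res.method)
        ax.axhline(0, color="0.8", lw=0.8)
        ax.set_xlabel("effect on exposure (SD/allele)")
        ax.set_ylabel("effect on outcome")
        if results:
            ax.legend(frameon=False, fontsize=8)
        return ax


class MultivariableMR:
    """Model object for multivariable MR (mediation-style adjustment)."""

    def __init__(self, instruments: InstrumentSet):
        if instruments.exposures is None:
            raise ValueError("instrument set has no exposure matrix")
        self.instruments = instruments

    def fit(self) -> MVMRResults:
        return mr_multivariable(self.instruments)
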