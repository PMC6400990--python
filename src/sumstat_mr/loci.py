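"""Locus discovery: distance clumping, approximate conditional/joint
(COJO-style) selection against an LD reference, LD pruning and variance
explained.

The joint analysis reconstructs the multiple-regression normal equations
from marginal summary statistics plus an external LD correlation matrix:
with per-variant dosage variance ``v_j = 2 p_j (1 - p_j)`` and reference
correlations ``R``,

    (X'X)_jk ~= sqrt(n_j v_j) sqrt(n_k v_k) R_jk
    (X'y)_j  ~= n_j v_j beta_j

and joint effects ``(X'X)^-1 X'y``.  The residual variance is estimated
robustly as the median over members of ``v_j beta_j^2 + v_j n_j se_j^2``
(each term is an estimate of the phenotypic variance implied by one
marginal fit).  Accuracy is bounded by how well the reference LD matches
the discovery sample; the contract is agreement with brute-force multiple
regression on the generating genotypes, not bit-compatibility with any
external tool.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import z_to_p

__all__ = [
    "LDReference",
    "Locus",
    "CollinearityError",
    "clump",
    "cojo_joint",
    "cojo_stepwise",
    "prune_selected",
    "variance_explained",
    "cumulative_variance_explained",
]


class CollinearityError(ValueError):
    """LD submatrix numerically singular for the requested variants."""


@dataclass
class LDReference:
    """Square LD correlation matrix with a variant sidecar.

    ``R`` is the dosage correlation matrix (unit diagonal, symmetric),
    ``eaf`` per-variant effect-allele frequencies in the reference, and
    ``dprime`` an optional |D'| matrix of the same shape.
    """

    variant_ids: list
    R: np.ndarray
    eaf: np.ndarray
    n_ref: int = 0
    dprime: np.ndarray | None = None
    sidecar: pd.DataFrame | None = None

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.eaf = np.asarray(self.eaf, dtype=float)
        m = len(self.variant_ids)
        if self.R.shape != (m, m):
            raise ValueError("R shape does not match variant_ids")
        if len(self.eaf) != m:
            raise ValueError("eaf length does not match variant_ids")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValueError("R diagonal must be 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def index(self, variant_id: str) -> int:
        return self._index[variant_id]

    def r2(self, a: str, b: str) -> float:
        return float(self.R[self.index(a), self.index(b)] ** 2)

    def dprime_between(self, a: str, b: str) -> float:
        if self.dprime is None:
            raise ValueError("no D' matrix attached")
        return float(self.dprime[self.index(a), self.index(b)])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = [self.index(v) for v in ids]
        return self.R[np.ix_(idx, idx)]

    # -- plain-text persistence: matrix TSV + sidecar TSV ---------------
    def to_files(self, matrix_path, sidecar_path, dprime_path=None) -> None:
        np.savetxt(matrix_path, self.R, delimiter="\t", fmt="%.10g")
        side = self.sidecar
        if side is None:
            side = pd.DataFrame({"SNP": self.variant_ids, "CHR": "NA",
                                 "POS": 0, "EA": "NA", "OA": "NA",
                                 "EAF": self.eaf})
        side.to_csv(sidecar_path, sep="\t", index=False)
        if dprime_path is not None and self.dprime is not None:
            np.savetxt(dprime_path, self.dprime, delimiter="\t", fmt="%.10g")

    @classmethod
    def from_files(cls, matrix_path, sidecar_path, dprime_path=None,
                   n_ref: int = 0) -> "LDReference":
        R = np.atleast_2d(np.loadtxt(matrix_path, delimiter="\t"))
        side = pd.read_csv(sidecar_path, sep="\t")
        dprime = None
        if dprime_path is not None and Path(dprime_path).exists():
            dprime = np.atleast_2d(np.loadtxt(dprime_path, delimiter="\t"))
        return cls(variant_ids=list(side["SNP"]), R=R,
                   eaf=side["EAF"].to_numpy(dtype=float), n_ref=n_ref,
                   dprime=dprime, sidecar=side)


@dataclass
class Locus:
    """A lead variant with its window and conditionally independent
    secondary signals."""

    lead: pd.Series
    window_start: int
    window_end: int
    members: pd.DataFrame
    secondary: pd.DataFrame | None = None

    @property
    def n_signals(self) -> int:
        return 1 + (0 if self.secondary is None else len(self.secondary))


def clump(meta: pd.DataFrame, p_thresh: float = 5e-8,
          half_window: int = 500_000,
          special_windows: Mapping[str, int] | None = None) -> list:
    """Greedy distance-based clumping of significant variants.

    ``meta`` needs columns snp, chrom, pos and a p column (``p_meta`` or
    ``p``).  Repeatedly promotes the most significant remaining variant
    to lead and absorbs every variant on the same chromosome within
    ``half_window`` bp on either side (``special_windows`` maps specific
    lead IDs to a wider half-window, for loci with very broad signals).
    Ties in p are broken by ascending position then lexicographic ID for
    determinism.
    """
    special_windows = dict(special_windows or {})
    pcol = "p_meta" if "p_meta" in meta.columns else "p"
    sig = meta[meta[pcol] < p_thresh].copy()
    sig = sig.sort_values([pcol, "pos", "snp"], kind="mergesort").reset_index(drop=True)
    remaining = sig
    loci: list[Locus] = []
    while len(remaining):
        lead = remaining.iloc[0]
        half = int(special_windows.get(lead["snp"], half_window))
        lo, hi = int(lead["pos"]) - half, int(lead["pos"]) + half
        in_win = (
            (remaining["chrom"].astype(str) == str(lead["chrom"]))
            & (remaining["pos"] >= lo) & (remaining["pos"] <= hi)
        )
        members = remaining.loc[in_win].reset_index(drop=True)
        loci.append(Locus(lead=lead, window_start=lo, window_end=hi,
                          members=members))
        remaining = remaining.loc[~in_win].reset_index(drop=True)
    return loci


def _joint_fit(members: pd.DataFrame, ld: LDReference):
    ids = list(members["snp"])
    idx = [ld.index(v) for v in ids]
    eaf = members["eaf"].to_numpy(dtype=float)
    use_ref = ~np.isfinite(eaf)
    eaf[use_ref] = ld.eaf[np.asarray(idx)][use_ref]
    v = 2.0 * eaf * (1.0 - eaf)
    n = members["n"].to_numpy(dtype=float)
    beta = members["beta"].to_numpy(dtype=float)
    se = members["se"].to_numpy(dtype=float)
    R = ld.submatrix(ids)

    cond = np.linalg.cond(R)
    if cond > 1e8:
        # name the worst offending pair
        A = np.abs(R - np.eye(len(ids)))
        j, k = np.unravel_index(np.argmax(A), A.shape)
        raise CollinearityError(
            f"LD submatrix singular (cond {cond:.3g}); worst pair "
            f"{ids[j]} / {ids[k]} with r = {R[j, k]:.4f}"
        )
    d = np.sqrt(n * v)
    xtx = R * np.outer(d, d)
    xty = n * v * beta
    beta_joint = np.linalg.solve(xtx, xty)
    sigma2 = float(np.median(v * beta**2 + v * n * se**2))
    cov = sigma2 * np.linalg.inv(xtx)
    se_joint = np.sqrt(np.diag(cov))
    return beta_joint, se_joint


def cojo_joint(members: pd.DataFrame, ld: LDReference) -> pd.DataFrame:
    """Approximate joint association model for a set of variants.

    ``members`` needs columns snp, beta, se, n and (optionally) eaf;
    frequencies fall back to the LD reference.  Returns a copy with
    ``beta_joint``, ``se_joint`` and ``p_joint`` columns (two-sided
    normal).
    """
    if members.empty:
        raise ValueError("no members to fit")
    beta_joint, se_joint = _joint_fit(members, ld)
    out = members.copy().reset_index(drop=True)
    out["beta_joint"] = beta_joint
    out["se_joint"] = se_joint
    out["p_joint"] = z_to_p(beta_joint / se_joint)
    return out


def cojo_stepwise(locus_members: pd.DataFrame, ld: LDReference,
                  p_joint_thresh: float = 5e-8,
                  r2_collinear: float = 0.9,
                  maf_min: float = 0.01) -> pd.DataFrame:
    """Forward stepwise selection of conditionally independent signals.

    Seeds the model with the locus lead (smallest marginal p), then at
    each step fits each remaining candidate jointly with the selected set
    and adds the one with the smallest conditional p if its joint p is
    below ``p_joint_thresh`` and its r^2 with every selected variant does
    not exceed ``r2_collinear``.  After each addition the model is
    re-fitted and any selected variant whose joint p rises above the
    threshold is dropped.  Candidates with reference MAF below
    ``maf_min`` are excluded up front.
    """
    pcol = "p_meta" if "p_meta" in locus_members.columns else "p"
    cand = locus_members.copy().reset_index(drop=True)
    eaf = cand["eaf"].to_numpy(dtype=float)
    ref_eaf = np.array([ld.eaf[ld.index(v)] for v in cand["snp"]])
    eaf = np.where(np.isfinite(eaf), eaf, ref_eaf)
    cand = cand.loc[np.minimum(eaf, 1 - eaf) >= maf_min].reset_index(drop=True)
    if cand.empty:
        return cand
    cand = cand.sort_values([pcol, "pos", "snp"], kind="mergesort").reset_index(drop=True)
    selected = [cand.iloc[0]["snp"]]
    pool = list(cand.iloc[1:]["snp"])

    def fit(ids):
        return cojo_joint(cand[cand["snp"].isin(ids)].copy(), ld)

    while True:
        best = None
        for c in pool:
            if any(ld.r2(c, s) > r2_collinear for s in selected):
                continue
            try:
                trial = fit(selected + [c])
            except CollinearityError:
                continue
            p_c = float(trial.loc[trial["snp"] == c, "p_joint"].iloc[0])
            if best is None or p_c < best[1]:
                best = (c, p_c)
        if best is None or best[1] >= p_joint_thresh:
            break
        selected.append(best[0])
        pool.remove(best[0])
        # backward pass: drop anything no longer significant jointly
        while True:
            model = fit(selected)
            worst = model.sort_values("p_joint", ascending=False).iloc[0]
            if float(worst["p_joint"]) >= p_joint_thresh and len(selected) > 1:
                selected.remove(worst["snp"])
            else:
                break
    model = fit(selected)
    # stable order: selection order
    order = {s: i for i, s in enumerate(selected)}
    return model.sort_values(by="snp", key=lambda s: s.map(order)).reset_index(drop=True)


def prune_selected(selected: pd.DataFrame, ld: LDReference,
                   r2_max: float = 0.05,
                   dprime_max: float = 0.95,
                   sentinel: str | None = None,
                   low_freq_maf: float = 0.05) -> pd.DataFrame:
    """LD-prune a set of selected signals.

    First a greedy r^2 prune: ordered by ascending joint p, keep the most
    significant and drop any later variant with r^2 strictly above
    ``r2_max`` to a kept one.  Then, if ``sentinel`` names the locus's
    common sentinel variant and a D' matrix is attached, low-frequency
    variants (reference MAF < ``low_freq_maf``) with |D'| to the sentinel
    above ``dprime_max`` are dropped.  The D' cutoff direction is
    configurable because conventions differ; the default drops
    high-|D'| (haplotype-sharing) variants.
    """
    pcol = "p_joint" if "p_joint" in selected.columns else "p"
    df = selected.sort_values([pcol, "snp"], kind="mergesort").reset_index(drop=True)
    kept: list[str] = []
    for snp in df["snp"]:
        if all(ld.r2(snp, k) <= r2_max for k in kept):
            kept.append(snp)
    out = df[df["snp"].isin(kept)].reset_index(drop=True)
    if sentinel is not None and ld.dprime is not None:
        maf = np.array([min(ld.eaf[ld.index(s)], 1 - ld.eaf[ld.index(s)])
                        for s in out["snp"]])
        dp = np.array([abs(ld.dprime_between(s, sentinel)) if s != sentinel
                       else 0.0 for s in out["snp"]])
        drop = (maf < low_freq_maf) & (dp > dprime_max)
        out = out.loc[~drop].reset_index(drop=True)
    return out


def variance_explained(beta_std: float, eaf: float) -> float:
    """Fraction of trait variance explained by one biallelic variant.

    For a standardized trait and per-allele effect ``beta_std`` in trait
    SD units, the variant's dosage variance is ``2 p (1 - p)`` and the
    explained fraction is ``2 p (1 - p) beta_std^2``.  Invariant under
    (eaf, beta) -> (1 - eaf, -beta).
    """
    if not 0.0 < eaf < 1.0:
        raise ValueError("eaf must lie strictly between 0 and 1")
    return 2.0 * eaf * (1.0 - eaf) * beta_std**2


def cumulative_variance_explained(betas: Sequence[float],
                                  eafs: Sequence[float]) -> np.ndarray:
    """Cumulative variance explained by independent variants (running
    sum; non-decreasing)."""
    vals = [variance_explained(b, p) for b, p in zip(betas, eafs)]
    return np.cumsum(vals)
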