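"""Conditional false discovery rate and stratified true-discovery-rate curves.

The conditional FDR re-ranks a primary trait's p-values within nested SNP
subsets selected by the conditioning trait's q-value.  When the two traits
share causal architecture, SNPs associated with the conditioning trait are
enriched for true primary-trait signal, so restricting the
Benjamini-Hochberg (BH) procedure to such a subset can push a SNP below the
5% FDR line that the genome-wide procedure would miss.  Each SNP reports the
minimum within-subset q-value across all conditioning subsets containing it
("significant ... conditioned on any subset"); the full set (level 1) is
always included, so the conditional q can never exceed the unconditional q.

Stratified TDR curves summarise the same enrichment non-parametrically: for
the SNPs whose conditioning-trait p falls below a stratum cutoff, the
conservative per-threshold true discovery rate is 1 - t / F(t), where F is
the stratum's empirical CDF of primary p-values, clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the 14 default conditioning q-value cutoffs
DEFAULT_LEVELS: tuple[float, ...] = (
    1e-5, 1e-4, 1e-3, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0
)

#: default conditioning-trait p cutoffs for TDR strata (loosest first)
DEFAULT_STRATA: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * n / j over the ascending order statistics,
    capped at 1 and mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CfdrTable:
    """Per-SNP conditional q-values over a ladder of conditioning subsets."""

    df: pd.DataFrame          # snp, q_unconditional, q_conditional_min, best_level, significant
    levels: tuple[float, ...]
    alpha: float

    def discoveries(self) -> pd.DataFrame:
        return self.df[self.df["significant"]].reset_index(drop=True)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def conditional_fdr(primary_p: np.ndarray, conditioning_q: np.ndarray,
                    levels: tuple[float, ...] = DEFAULT_LEVELS,
                    alpha: float = 0.05,
                    snp_ids=None) -> CfdrTable:
    """Minimum within-subset BH q-value per SNP across conditioning subsets.

    For each level c the subset S_c = {SNP : conditioning_q <= c} gets its
    own BH pass over the primary p-values restricted to S_c; a SNP's
    conditional q is the minimum over the levels whose subset contains it.
    Empty subsets are skipped.  Vectors must be aligned on the same
    (clumped) SNP set.
    """
    primary_p = np.asarray(primary_p, dtype=float)
    conditioning_q = np.asarray(conditioning_q, dtype=float)
    if primary_p.shape != conditioning_q.shape:
        raise ValueError("primary_p and conditioning_q must be aligned")
    levels = tuple(sorted(float(c) for c in levels))
    if levels[-1] != 1.0:
        raise ValueError("the last conditioning level must be 1 (the full set)")

    n = primary_p.size
    q_uncond = bh_qvalues(primary_p)
    q_min = np.full(n, np.inf)
    best_level = np.full(n, np.nan)
    for c in levels:
        members = conditioning_q <= c
        if not members.any():
            continue
        q_sub = bh_qvalues(primary_p[members])
        improved = np.zeros(n, dtype=bool)
        improved[members] = q_sub < q_min[members]
        q_full = np.full(n, np.inf)
        q_full[members] = q_sub
        best_level = np.where(improved, c, best_level)
        q_min = np.minimum(q_min, q_full)

    df = pd.DataFrame({
        "snp": snp_ids if snp_ids is not None else np.arange(n),
        "p_primary": primary_p,
        "q_conditioning": conditioning_q,
        "q_unconditional": q_uncond,
        "q_conditional_min": q_min,
        "best_level": best_level,
        "significant": q_min <= alpha,
    })
    return CfdrTable(df=df, levels=levels, alpha=alpha)


@dataclass
class TdrCurve:
    """One stratum's conservative TDR curve.

    ``tdr[k]`` = max(0, 1 - eval_grid[k] / F(eval_grid[k])) where F is the
    self-inclusive empirical CDF of the stratum's primary p-values; grid
    points where F = 0 are omitted.
    """

    stratum_threshold: float
    eval_grid: np.ndarray
    tdr: np.ndarray
    n_stratum: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stratum": self.stratum_threshold,
            "neg_log10_p": -np.log10(self.eval_grid),
            "tdr": self.tdr,
        })


def stratified_tdr(primary_p: np.ndarray, conditioning_p: np.ndarray,
                   strata: tuple[float, ...] = DEFAULT_STRATA,
                   eval_grid: np.ndarray | None = None) -> list[TdrCurve]:
    """Conservative TDR curves per conditioning stratum.

    Strata are nested subsets {SNP : conditioning_p <= cutoff}.  With no
    ``eval_grid`` the curve is evaluated at the stratum's own sorted unique
    primary p-values (faithful per-SNP curves); pass a fixed grid for
    plot-ready matched curves.  Empty strata are omitted.
    """
    primary_p = np.asarray(primary_p, dtype=float)
    conditioning_p = np.asarray(conditioning_p, dtype=float)
    if primary_p.shape != conditioning_p.shape:
        raise ValueError("primary_p and conditioning_p must be aligned")

    curves: list[TdrCurve] = []
    for cutoff in strata:
        members = conditioning_p <= cutoff
        m = int(members.sum())
        if m == 0:
            continue
        p_sorted = np.sort(primary_p[members])
        grid = np.unique(p_sorted) if eval_grid is None else np.asarray(eval_grid, dtype=float)
        fhat = np.searchsorted(p_sorted, grid, side="right") / m
        defined = fhat > 0
        grid, fhat = grid[defined], fhat[defined]
        tdr = np.clip(1.0 - grid / fhat, 0.0, 1.0)
        curves.append(TdrCurve(stratum_threshold=float(cutoff), eval_grid=grid,
                               tdr=tdr, n_stratum=m))
    return curves


def variance_explained(effect: float, se: float, n: int) -> float:
    """Approximate % phenotypic variance explained by one SNP, from its Z.

    Uses the squared-correlation identity for a single regressor,
    r^2 = z^2 / (z^2 + n - 2), returned as a percentage.  Approximate: it
    assumes a continuous trait and one degree of freedom.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if n <= 2:
        raise ValueError("n must be > 2")
    z = effect / se
    return 100.0 * z * z / (z * z + n - 2)
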