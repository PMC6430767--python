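"""SNP effect concordance analysis (SECA).

Given a set of approximately independent index SNPs with p-values and effect
signs in two traits, SECA asks two questions over a grid of p-value cutoff
pairs (t1, t2):

* **pleiotropy** — are SNPs below both cutoffs over-represented relative to
  independent margins?  Each grid cell holds a 2x2 table of
  (p1 <= t1) x (p2 <= t2); the cell-level test is the one-sided
  hypergeometric (Fisher) tail for enrichment of the both-significant cell.
* **concordance** — among SNPs below both cutoffs, do effect signs agree
  more (or less) often than the 50% expected under independence?  The
  cell-level test is the exact binomial against 0.5, one-sided in each
  direction.

The grid-level summary statistic is the number of cells whose cell-level
p-value is at or below ``cell_alpha`` (0.05).  Its significance is assessed
by permutation: the secondary trait's (p, sign) pairs are randomly re-paired
across SNPs, which preserves each trait's marginal distributions exactly
while destroying any cross-trait linkage.  Empirical p-values use the
add-one rule (1 + exceedances) / (1 + permutations) and carry an exact 95%
Clopper-Pearson interval.  Concordance is reported as the better of the
excess/deficit one-sided results together with a direction label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

#: 12-level default cutoff set used for both traits (144 grid cells)
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0
)


@dataclass
class ThresholdGrid:
    thresholds_primary: tuple[float, ...] = DEFAULT_THRESHOLDS
    thresholds_secondary: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        for name, ts in (("primary", self.thresholds_primary),
                         ("secondary", self.thresholds_secondary)):
            ts = tuple(float(t) for t in ts)
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError(f"{name} thresholds must be strictly ascending")
            if ts[0] <= 0 or ts[-1] != 1.0:
                raise ValueError(f"{name} thresholds must lie in (0,1] and end at 1.0")
        self.thresholds_primary = tuple(float(t) for t in self.thresholds_primary)
        self.thresholds_secondary = tuple(float(t) for t in self.thresholds_secondary)


@dataclass
class SecaSummary:
    """Permutation summary for one trait pair and one mode."""

    mode: str                      # "pleiotropy" or "concordance"
    statistic_observed: int        # grid cells with cell-level p <= cell_alpha
    empirical_p: float
    ci_low: float
    ci_high: float
    direction: str                 # "+", "-", or "none"
    n_perm: int

    def __post_init__(self) -> None:
        assert 0.0 < self.empirical_p <= 1.0
        assert self.ci_low <= self.empirical_p <= self.ci_high


def _indicator_matrices(variants: pd.DataFrame, grid: ThresholdGrid):
    p1 = variants["p1"].to_numpy(dtype=float)
    p2 = variants["p2"].to_numpy(dtype=float)
    t1 = np.asarray(grid.thresholds_primary)
    t2 = np.asarray(grid.thresholds_secondary)
    A1 = p1[:, None] <= t1[None, :]
    A2 = p2[:, None] <= t2[None, :]
    return A1, A2


def pleiotropy_grid(variants: pd.DataFrame, grid: ThresholdGrid | None = None) -> pd.DataFrame:
    """Per-cell 2x2 counts and one-sided hypergeometric enrichment p-values.

    Returns a long-format DataFrame with one row per (t1, t2) cell.
    """
    if variants.empty:
        raise ValueError("no variants")
    grid = grid or ThresholdGrid()
    A1, A2 = _indicator_matrices(variants, grid)
    n = len(variants)
    n_row = A1.sum(axis=0)
    n_col = A2.sum(axis=0)
    n_both = A1.T.astype(np.int64) @ A2.astype(np.int64)

    rows = []
    for i, t1 in enumerate(grid.thresholds_primary):
        for j, t2 in enumerate(grid.thresholds_secondary):
            k = int(n_both[i, j])
            # P(X >= k) for X ~ Hypergeom(N=n, K=n_row, draws=n_col)
            p_enrich = float(stats.hypergeom.sf(k - 1, n, int(n_row[i]), int(n_col[j])))
            rows.append({
                "t1": t1, "t2": t2,
                "n_both": k,
                "n_only1": int(n_row[i]) - k,
                "n_only2": int(n_col[j]) - k,
                "n_neither": n - int(n_row[i]) - int(n_col[j]) + k,
                "enrichment_p": min(p_enrich, 1.0),
            })
    return pd.DataFrame(rows)


def concordance_grid(variants: pd.DataFrame, grid: ThresholdGrid | None = None) -> pd.DataFrame:
    """Per-cell sign-agreement counts and one-sided exact binomial p-values.

    For each cell the SNPs with p1 <= t1 and p2 <= t2 are classified as
    concordant (sign1 == sign2) or discordant; ``concordance_p_excess`` is
    P(X >= k | n, 1/2) and ``concordance_p_deficit`` is P(X <= k | n, 1/2).
    Empty cells get both p-values equal to 1 and are non-informative.
    """
    if variants.empty:
        raise ValueError("no variants")
    grid = grid or ThresholdGrid()
    A1, A2 = _indicator_matrices(variants, grid)
    agree = (variants["sign1"].to_numpy() == variants["sign2"].to_numpy())
    n_both = A1.T.astype(np.int64) @ A2.astype(np.int64)
    n_conc = (A1 & agree[:, None]).T.astype(np.int64) @ A2.astype(np.int64)

    rows = []
    for i, t1 in enumerate(grid.thresholds_primary):
        for j, t2 in enumerate(grid.thresholds_secondary):
            nb = int(n_both[i, j])
            k = int(n_conc[i, j])
            if nb == 0:
                p_exc = p_def = 1.0
            else:
                p_exc = float(stats.binom.sf(k - 1, nb, 0.5))
                p_def = float(stats.binom.cdf(k, nb, 0.5))
            rows.append({
                "t1": t1, "t2": t2,
                "n_both": nb,
                "n_concordant": k,
                "n_discordant": nb - k,
                "concordance_p_excess": min(p_exc, 1.0),
                "concordance_p_deficit": min(p_def, 1.0),
            })
    return pd.DataFrame(rows)


def _hypergeom_crit(n: int, n_row: np.ndarray, n_col: np.ndarray, alpha: float) -> np.ndarray:
    """Smallest overlap count per cell whose enrichment p is <= alpha.

    crit[i,j] is the minimal m with P(X >= m) <= alpha; cells where even the
    maximal overlap is not significant get crit = max_overlap + 1.
    """
    crit = np.empty((len(n_row), len(n_col)), dtype=np.int64)
    for i, K in enumerate(n_row):
        for j, d in enumerate(n_col):
            m_max = int(min(K, d))
            ks = np.arange(0, m_max + 1)
            sf = stats.hypergeom.sf(ks - 1, n, int(K), int(d))  # P(X >= k)
            sig = np.flatnonzero(sf <= alpha)
            crit[i, j] = int(ks[sig[0]]) if sig.size else m_max + 1
    return crit


def _binom_crit(n_max: int, alpha: float) -> np.ndarray:
    """For each n in 0..n_max, the smallest k with P(Bin(n,1/2) >= k) <= alpha.

    Returns n+1 (impossible) where no k qualifies (including n = 0).
    """
    crit = np.empty(n_max + 1, dtype=np.int64)
    ns = np.arange(n_max + 1)
    # start from the continuity-corrected quantile, then fix up discretely
    guess = np.ceil(stats.binom.isf(alpha, np.maximum(ns, 1), 0.5)).astype(np.int64)
    for n, g in zip(ns, guess):
        k = max(0, min(int(g) - 2, n))
        while k <= n and stats.binom.sf(k - 1, n, 0.5) > alpha:
            k += 1
        crit[n] = k  # == n+1 when unattainable
    return crit


def _clopper_pearson(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="beta")
    return float(lo), float(hi)


def _direction_label(variants: pd.DataFrame, grid: ThresholdGrid) -> str:
    """Sign of the concordant-minus-discordant excess over informative cells.

    Falls back to the (1.0, 1.0) cell when the grid total is zero; "none"
    only when no cell is informative.
    """
    cg = concordance_grid(variants, grid)
    informative = cg[cg["n_both"] > 0]
    if informative.empty:
        return "none"
    total = int((informative["n_concordant"] - informative["n_discordant"]).sum())
    if total == 0:
        full = cg[(cg["t1"] == 1.0) & (cg["t2"] == 1.0)].iloc[0]
        total = int(full["n_concordant"] - full["n_discordant"])
    if total > 0:
        return "+"
    if total < 0:
        return "-"
    return "none"


class _BinomTailHalf:
    """Cached exact upper tails P(Bin(n, 1/2) >= k), vectorized over cells."""

    def __init__(self) -> None:
        self._tails: dict[int, np.ndarray] = {}

    def _table(self, n: int) -> np.ndarray:
        tab = self._tails.get(n)
        if tab is None:
            from scipy.special import gammaln
            ks = np.arange(n + 1)
            pmf = np.exp(gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1)
                         - n * np.log(2.0))
            tab = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
            self._tails[n] = tab
        return tab

    def __call__(self, n_both: np.ndarray, k: np.ndarray) -> np.ndarray:
        out = np.ones(n_both.shape)
        for nn in np.unique(n_both):
            if nn == 0:
                continue
            mask = n_both == nn
            out[mask] = self._table(int(nn))[k[mask]]
        return out


def permutation_summary(variants: pd.DataFrame, grid: ThresholdGrid | None = None,
                        mode: str = "pleiotropy", n_perm: int = 9999,
                        seed: int | np.random.Generator | None = 0,
                        cell_alpha: float = 0.05,
                        summary: str = "min_p") -> SecaSummary:
    """Permutation-based empirical p for the grid-level SECA statistic.

    The null re-pairs the secondary trait's (p, sign) pairs across SNPs,
    which preserves each trait's marginals exactly.  Two grid summaries are
    available: ``"min_p"`` (default) uses the smallest cell-level p across
    the grid, which takes many distinct values and yields a near-uniform
    null; ``"count"`` uses the number of cells with cell-level p at or below
    ``cell_alpha``, which is coarser (large null atom at zero significant
    cells) but matches the cited method's presentation.

    For concordance the summary is evaluated separately in the excess and
    deficit directions and the smaller empirical p is reported; the
    direction label is the sign of the overall concordant-discordant excess,
    computed on the observed data, never on permutations.
    """
    if mode not in ("pleiotropy", "concordance"):
        raise ValueError(f"unknown mode {mode!r}")
    if summary not in ("min_p", "count"):
        raise ValueError(f"unknown summary {summary!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 19:
        import warnings
        warnings.warn(f"n_perm={n_perm} gives resolution {1/(1+n_perm):.2g}; "
                      "empirical p cannot fall below that")
    grid = grid or ThresholdGrid()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    A1, A2 = _indicator_matrices(variants, grid)
    A1f = A1.astype(np.float64)
    A2f = A2.astype(np.float64)
    n = len(variants)

    if mode == "pleiotropy":
        n_row = A1.sum(axis=0)
        n_col = A2.sum(axis=0)
        if summary == "count":
            crit = _hypergeom_crit(n, n_row, n_col, cell_alpha)

            def stat(n_both):
                return int((n_both >= crit).sum())
        else:
            # per-cell enrichment sf lookup, indexed by overlap count; the
            # margins are permutation-invariant so this is computed once
            flat_tables = [stats.hypergeom.sf(np.arange(min(K, d) + 1) - 1, n, int(K), int(d))
                           for K in n_row for d in n_col]

            def stat(n_both):
                # larger statistic = stronger enrichment
                return -min(tab[c] for tab, c in zip(flat_tables, n_both.ravel()))

        def n_both_of(A2p):
            return np.rint(A1f.T @ A2p).astype(np.int64)

        observed = stat(n_both_of(A2f))
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if stat(n_both_of(A2f[perm])) >= observed:
                exceed += 1
        empirical_p = (1 + exceed) / (1 + n_perm)
        ci_low, ci_high = _clopper_pearson(1 + exceed, 1 + n_perm)
        direction = _direction_label(variants, grid)
        obs_count = observed if summary == "count" else int(
            (n_both_of(A2f) >= _hypergeom_crit(n, n_row, n_col, cell_alpha)).sum())
        return SecaSummary("pleiotropy", obs_count, empirical_p, ci_low, ci_high,
                           direction, n_perm)

    # concordance
    kcrit = _binom_crit(n, cell_alpha)
    sign1 = variants["sign1"].to_numpy()
    sign2 = variants["sign2"].to_numpy()
    bin_tail = _BinomTailHalf()

    def cell_counts(A2p, agree):
        n_both = np.rint(A1f.T @ A2p).astype(np.int64)
        n_conc = np.rint((A1f * agree[:, None]).T @ A2p).astype(np.int64)
        return n_both, n_conc

    def stats_pair(A2p, agree):
        n_both, n_conc = cell_counts(A2p, agree)
        if summary == "count":
            c = kcrit[n_both]
            return int((n_conc >= c).sum()), int(((n_both - n_conc) >= c).sum())
        p_exc = bin_tail(n_both, n_conc)
        p_def = bin_tail(n_both, n_both - n_conc)
        return -p_exc.min(), -p_def.min()

    obs_exc, obs_def = stats_pair(A2f, (sign1 == sign2).astype(np.float64))
    exceed_exc = exceed_def = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s_exc, s_def = stats_pair(A2f[perm], (sign1 == sign2[perm]).astype(np.float64))
        exceed_exc += s_exc >= obs_exc
        exceed_def += s_def >= obs_def
    p_exc = (1 + exceed_exc) / (1 + n_perm)
    p_def = (1 + exceed_def) / (1 + n_perm)
    if p_exc <= p_def:
        empirical_p, exceed, agree_obs = p_exc, exceed_exc, True
    else:
        empirical_p, exceed, agree_obs = p_def, exceed_def, False
    n_both_obs, n_conc_obs = cell_counts(A2f, (sign1 == sign2).astype(np.float64))
    c = kcrit[n_both_obs]
    obs_count = int((n_conc_obs >= c).sum()) if agree_obs else int(
        ((n_both_obs - n_conc_obs) >= c).sum())
    ci_low, ci_high = _clopper_pearson(1 + exceed, 1 + n_perm)
    direction = _direction_label(variants, grid)
    return SecaSummary("concordance", obs_count, empirical_p, ci_low, ci_high,
                       direction, n_perm)


@dataclass
class SecaResult:
    """Full SECA output for one trait pair."""

    trait1: str
    trait2: str
    n_harmonized: int
    n_index: int
    pleiotropy: SecaSummary
    concordance: SecaSummary
    pleiotropy_cells: pd.DataFrame
    concordance_cells: pd.DataFrame
    index_variants: pd.DataFrame

    def row(self) -> dict:
        """One row in the trait-pair results table schema."""
        return {
            "trait1": self.trait1,
            "trait2": self.trait2,
            "n_index_snps": self.n_index,
            "p_pleiotropy": self.pleiotropy.empirical_p,
            "ci_pleiotropy_low": self.pleiotropy.ci_low,
            "ci_pleiotropy_high": self.pleiotropy.ci_high,
            "p_concordance": self.concordance.empirical_p,
            "ci_concordance_low": self.concordance.ci_low,
            "ci_concordance_high": self.concordance.ci_high,
            "direction": self.concordance.direction,
        }


def run_seca(primary, secondary, ld, clump_config=None, grid: ThresholdGrid | None = None,
             n_perm: int = 9999, seed: int = 0, drop_palindromic: bool = True) -> SecaResult:
    """harmonize -> clump (ranking on the secondary trait) -> grids -> permutation.

    ``primary`` and ``secondary`` are SumStats; ``ld`` an LdReference.
    """
    from .clump import ClumpConfig, clump as _clump
    from .sumstats import harmonize

    grid = grid or ThresholdGrid()
    harmonized = harmonize(primary, secondary, drop_palindromic=drop_palindromic)
    cfg = clump_config or ClumpConfig()
    clumped = _clump(harmonized, ld, cfg, conditioning_label=secondary.trait_label)
    idx = clumped.index_df
    rng = np.random.default_rng(seed)
    pleio = permutation_summary(idx, grid, "pleiotropy", n_perm=n_perm, seed=rng)
    conc = permutation_summary(idx, grid, "concordance", n_perm=n_perm, seed=rng)
    return SecaResult(
        trait1=primary.trait_label,
        trait2=secondary.trait_label,
        n_harmonized=len(harmonized),
        n_index=len(idx),
        pleiotropy=pleio,
        concordance=conc,
        pleiotropy_cells=pleiotropy_grid(idx, grid),
        concordance_cells=concordance_grid(idx, grid),
        index_variants=idx,
    )
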