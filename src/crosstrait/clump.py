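"""Greedy LD clumping of a harmonized SNP set.

Clumping reduces the genome-wide SNP set to approximately independent index
SNPs: variants are ranked by one trait's p-value and, starting from the most
significant, each chosen index removes every remaining SNP on the same
chromosome within a +/-window that is in LD (r^2 above a threshold) with it.
The defaults (500 kb window, r^2 > 0.2, ranking on the conditioning trait)
match standard PLINK-style practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class LdReference:
    """Pairwise r^2 lookup; absent pairs are treated as r^2 = 0.

    Keys are unordered SNP-id pairs; symmetry is enforced at construction.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        self._neighbors: dict[str, set[str]] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r^2 out of [0,1] for pair ({a},{b}): {r2}")
        if a == b:
            return
        key = self._key(a, b)
        prev = self._r2.get(key)
        if prev is not None and abs(prev - r2) > 1e-9:
            raise ValueError(f"conflicting r^2 for pair {key}: {prev} vs {r2}")
        self._r2[key] = float(r2)
        self._neighbors.setdefault(a, set()).add(b)
        self._neighbors.setdefault(b, set()).add(a)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def neighbors(self, snp: str) -> set[str]:
        return self._neighbors.get(snp, set())

    def __contains__(self, snp: str) -> bool:
        return snp in self._neighbors

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def read_table(cls, path) -> "LdReference":
        """Read a PLINK-style pairwise table with columns SNP_A, SNP_B, R2."""
        df = pd.read_csv(path, sep=r"\s+")
        for col in ("SNP_A", "SNP_B", "R2"):
            if col not in df.columns:
                raise ValueError(f"{path}: LD table missing column {col}")
        ld = cls()
        for a, b, r2 in zip(df["SNP_A"].astype(str), df["SNP_B"].astype(str),
                            pd.to_numeric(df["R2"])):
            ld.add(a, b, float(r2))
        return ld

    def write_table(self, path) -> None:
        rows = sorted(self._r2.items())
        df = pd.DataFrame(
            {"SNP_A": [k[0] for k, _ in rows],
             "SNP_B": [k[1] for k, _ in rows],
             "R2": [v for _, v in rows]}
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class ClumpConfig:
    window_bp: int = 500_000       # +/- half-width around the index SNP
    r2_threshold: float = 0.2      # exclusion requires r^2 strictly above this
    ranking_trait: str = "secondary"  # {"primary", "secondary"}

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in [0,1]")
        if self.ranking_trait not in ("primary", "secondary"):
            raise ValueError("ranking_trait must be 'primary' or 'secondary'")


@dataclass
class ClumpIndexSet:
    """Result of clumping: index rows plus the number of removed SNPs."""

    conditioning_label: str
    index_df: pd.DataFrame
    removed_count: int

    @property
    def index_keys(self) -> list[str]:
        return self.index_df["snp"].tolist()

    def write(self, path) -> None:
        self.index_df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def clump(variants: pd.DataFrame, ld: LdReference,
          config: ClumpConfig | None = None,
          conditioning_label: str = "") -> ClumpIndexSet:
    """Greedy clumping of harmonized variants (columns snp, chr, bp, p1, p2).

    SNPs are processed in ascending order of the ranking trait's p-value
    (ties broken by chromosome, position, then SNP id).  Each SNP not yet
    removed becomes an index and removes all remaining non-index SNPs on the
    same chromosome within +/-window_bp whose r^2 with it exceeds the
    threshold.  SNPs absent from the LD reference have r^2 = 0 with
    everything and form their own clumps.
    """
    if config is None:
        config = ClumpConfig()
    if variants.empty:
        raise ValueError("no variants to clump")
    rank_col = "p1" if config.ranking_trait == "primary" else "p2"
    if rank_col not in variants.columns:
        raise ValueError(f"ranking column {rank_col!r} missing")

    df = variants.reset_index(drop=True)
    snp = df["snp"].to_numpy()
    chrom = df["chr"].astype(str).to_numpy()
    bp = df["bp"].to_numpy(dtype=np.int64)
    p_rank = df[rank_col].to_numpy(dtype=float)

    n = len(df)
    order = np.lexsort((snp, bp, chrom, p_rank))  # p, then chr/bp/snp for ties

    # per-chromosome position index for fast window queries
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos_order = idx[np.argsort(bp[idx], kind="mergesort")]
        by_chrom[c] = (bp[pos_order], pos_order)

    FREE, INDEX, REMOVED = 0, 1, 2
    status = np.zeros(n, dtype=np.int8)
    n_missing_ld = 0

    for i in order:
        if status[i] != FREE:
            continue
        status[i] = INDEX
        if snp[i] not in ld:
            n_missing_ld += 1
            continue
        pos_sorted, pos_order = by_chrom[chrom[i]]
        lo = np.searchsorted(pos_sorted, bp[i] - config.window_bp, side="left")
        hi = np.searchsorted(pos_sorted, bp[i] + config.window_bp, side="right")
        for j in pos_order[lo:hi]:
            if status[j] == FREE and ld.r2(snp[i], snp[j]) > config.r2_threshold:
                status[j] = REMOVED

    if n_missing_ld:
        logger.info("clump: %d index SNPs absent from the LD reference (own clumps)",
                    n_missing_ld)

    is_index = status == INDEX
    index_df = df[is_index].sort_values(["chr", "bp"], kind="mergesort").reset_index(drop=True)
    return ClumpIndexSet(
        conditioning_label=conditioning_label,
        index_df=index_df,
        removed_count=int(n - is_index.sum()),
    )
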