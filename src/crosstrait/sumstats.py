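"""Reading, validation and allele harmonization of GWAS summary statistics.

A summary-statistics table carries one row per SNP with the effect allele,
the other allele, a signed effect estimate (beta or Z) and a p-value.  Before
two studies can be compared SNP-by-SNP, their effect signs must refer to the
same allele: this module aligns alleles (handling swapped allele columns and
strand flips) and intersects tables onto a common SNP set.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default METAL/PLINK-style column names, overridable via ``column_map``
DEFAULT_COLUMNS: dict[str, str] = {
    "snp": "SNP",
    "chr": "CHR",
    "bp": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "FRQ",
    "effect": "BETA",
    "se": "SE",
    "p": "P",
}

MANDATORY_FIELDS = ("snp", "chr", "bp", "effect_allele", "other_allele", "effect", "p")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")

#: smallest p-value admitted; p = 0 in input is clamped here so that
#: ratio-based quantities (TDR, BH) stay defined
P_FLOOR = 1e-300


def normalize_chrom(chrom: pd.Series | str) -> pd.Series | str:
    """Normalize chromosome labels so that 'chr1', '1' and ' 1 ' compare equal."""
    if isinstance(chrom, str):
        c = chrom.strip()
        return c[3:] if c.lower().startswith("chr") else c
    s = chrom.astype(str).str.strip()
    return s.str.replace(r"^(?i:chr)", "", regex=True)


@dataclass
class SumStats:
    """A validated GWAS summary-statistics table.

    ``df`` uses canonical column names: snp, chr, bp, a1 (effect allele),
    a2 (other allele), eaf, beta, se, p.  Rows are sorted by (chr, bp).
    """

    trait_label: str
    df: pd.DataFrame
    effect_scale: str = "beta"  # {"beta", "z", "log-odds"}
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.effect_scale not in ("beta", "z", "log-odds"):
            raise ValueError(f"unknown effect scale {self.effect_scale!r}")

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> pd.DataFrame:
        return self.df[["snp", "chr", "bp"]]

    def write(self, path) -> None:
        out = self.df.rename(
            columns={
                "snp": "SNP", "chr": "CHR", "bp": "BP", "a1": "A1", "a2": "A2",
                "eaf": "FRQ", "beta": "BETA", "se": "SE", "p": "P",
            }
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sumstats(path, column_map: dict[str, str] | None = None,
                  effect_scale: str = "beta", trait_label: str | None = None) -> SumStats:
    """Read and validate a whitespace/tab-delimited summary-statistics file.

    Rows failing validation (unparseable numbers, p outside (0,1], bad
    alleles) are dropped and counted; a missing mandatory column or a
    duplicated SNP id is a hard error.  Gzip input is accepted.
    p-values of exactly 0 are clamped to ``P_FLOOR`` with a warning.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        raw = pd.read_csv(fh, sep=r"\s+", dtype=str)

    missing = [cols[f] for f in MANDATORY_FIELDS if cols[f] not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    rename = {cols[f]: canon for f, canon in
              zip(("snp", "chr", "bp", "effect_allele", "other_allele", "eaf", "effect", "se", "p"),
                  ("snp", "chr", "bp", "a1", "a2", "eaf", "beta", "se", "p"))
              if cols[f] in raw.columns}
    df = raw.rename(columns=rename)
    keep = [c for c in ("snp", "chr", "bp", "a1", "a2", "eaf", "beta", "se", "p") if c in df.columns]
    df = df[keep].copy()

    n_in = len(df)
    df["chr"] = normalize_chrom(df["chr"])
    df["bp"] = pd.to_numeric(df["bp"], errors="coerce")
    df["beta"] = pd.to_numeric(df["beta"], errors="coerce")
    df["p"] = pd.to_numeric(df["p"], errors="coerce").astype(float)
    for opt in ("eaf", "se"):
        if opt in df.columns:
            df[opt] = pd.to_numeric(df[opt], errors="coerce")
        else:
            df[opt] = np.nan
    df["a1"] = df["a1"].str.upper()
    df["a2"] = df["a2"].str.upper()

    n_zero_p = int((df["p"] == 0).sum())
    if n_zero_p:
        logger.warning("%s: %d p-values of exactly 0 clamped to %.3g", path, n_zero_p, P_FLOOR)
        df.loc[df["p"] == 0, "p"] = P_FLOOR

    valid = (
        df["snp"].notna() & (df["snp"] != "")
        & df["bp"].notna() & (df["bp"] >= 1)
        & df["beta"].notna()
        & df["p"].notna() & (df["p"] > 0) & (df["p"] <= 1)
        & df["a1"].isin(_VALID_ALLELES) & df["a2"].isin(_VALID_ALLELES)
        & (df["a1"] != df["a2"])
    )
    if "se" in df.columns:
        valid &= df["se"].isna() | (df["se"] > 0)
    n_dropped = int(n_in - valid.sum())
    if n_dropped:
        logger.warning("%s: dropped %d of %d rows failing validation", path, n_dropped, n_in)
    df = df[valid].copy()

    if df["snp"].duplicated().any():
        dups = df.loc[df["snp"].duplicated(), "snp"].head().tolist()
        raise ValueError(f"{path}: duplicate SNP id(s), e.g. {dups}")

    df["bp"] = df["bp"].astype(np.int64)
    df = df.sort_values(["chr", "bp"], kind="mergesort").reset_index(drop=True)
    label = trait_label if trait_label is not None else str(path)
    return SumStats(trait_label=label, df=df, effect_scale=effect_scale, n_dropped=n_dropped)


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT)


def harmonize(primary: SumStats, secondary: SumStats,
              drop_palindromic: bool = True,
              freq_rescue: bool = False,
              freq_margin: float = 0.08) -> pd.DataFrame:
    """Align the two tables onto shared SNPs with signs on a common allele.

    Returns a DataFrame with columns snp, chr, bp, p1, sign1, p2, sign2.
    The secondary sign is negated when its allele columns are swapped
    relative to the primary; strand flips (A<->T, C<->G) are resolved by
    complementing before matching.  Palindromic SNPs (A/T, C/G pairs) are
    strand-ambiguous and dropped by default; with ``freq_rescue`` they are
    kept when both studies report an allele frequency away from 0.5
    (|eaf - 0.5| > ``freq_margin``) and the frequencies identify the strand.
    SNPs whose allele pairs cannot be reconciled are dropped and counted.
    """
    m = primary.df.merge(secondary.df, on="snp", suffixes=("_1", "_2"), how="inner")
    if m.empty:
        raise ValueError(
            f"no overlapping SNPs between {primary.trait_label!r} and {secondary.trait_label!r}"
        )

    a1p, a2p = m["a1_1"], m["a2_1"]
    a1s, a2s = m["a1_2"], m["a2_2"]
    c1s, c2s = _complement(a1s), _complement(a2s)

    same = (a1s == a1p) & (a2s == a2p)
    swapped = (a1s == a2p) & (a2s == a1p)
    comp_same = (c1s == a1p) & (c2s == a2p)
    comp_swapped = (c1s == a2p) & (c2s == a1p)

    palindromic = a2p == a1p.map(_COMPLEMENT)

    flip = np.where(swapped | (comp_swapped & ~same & ~comp_same), -1.0, 1.0)
    matched = same | swapped | comp_same | comp_swapped

    if drop_palindromic:
        keep = matched & ~palindromic
        if freq_rescue:
            f1, f2 = m["eaf_1"], m["eaf_2"]
            informative = (
                f1.notna() & f2.notna()
                & ((f1 - 0.5).abs() > freq_margin) & ((f2 - 0.5).abs() > freq_margin)
            )
            # frequencies on the same side of 0.5 => effect alleles agree
            agree = (f1 < 0.5) == (f2 < 0.5)
            rescue = palindromic & matched & informative
            flip = np.where(rescue & ~agree, -1.0, np.where(rescue & agree, 1.0, flip))
            keep = keep | rescue
    else:
        keep = matched

    n_dropped = int(len(m) - keep.sum())
    if n_dropped:
        logger.info("harmonize: dropped %d of %d shared SNPs (palindromic/irreconcilable)",
                    n_dropped, len(m))

    out = pd.DataFrame({
        "snp": m["snp"],
        "chr": m["chr_1"],
        "bp": m["bp_1"],
        "p1": m["p_1"],
        "sign1": np.where(m["beta_1"] < 0, -1, 1).astype(np.int8),
        "p2": m["p_2"],
        "sign2": np.where(m["beta_2"] * flip < 0, -1, 1).astype(np.int8),
    })[keep.to_numpy()]
    if out.empty:
        raise ValueError("no SNPs survived allele harmonization")
    return out.sort_values(["chr", "bp"], kind="mergesort").reset_index(drop=True)


def intersect_all(tables: list[SumStats]) -> pd.DataFrame:
    """SNP keys (snp, chr, bp) present in every table, sorted by (chr, bp)."""
    if len(tables) < 2:
        raise ValueError("need at least two tables to intersect")
    common = set(tables[0].df["snp"])
    for t in tables[1:]:
        common &= set(t.df["snp"])
    if not common:
        raise ValueError("empty SNP intersection across tables")
    keys = tables[0].keys()
    out = keys[keys["snp"].isin(common)]
    return out.sort_values(["chr", "bp"], kind="mergesort").reset_index(drop=True)
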