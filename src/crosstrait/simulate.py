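"""Paired GWAS summary statistics over an LD-block genome with known truth.

The generator emulates the situation the analysis targets: two GWAS of
different traits over the same variants, where some LD blocks carry a causal
variant for one trait, the other, or both, and shared blocks agree in effect
sign with a controllable probability.  The genome is a set of independent
compound-symmetry LD blocks separated by gaps larger than the clumping
window, so "one index SNP per block" is the exact ground truth and every
pipeline stage is decidable against the emitted TruthRecord.

Per block one tag variant carries the causal effect beta ~ sign * |N(0,
effect_sd)|; the block's Z-scores are drawn from a multivariate normal with
mean sqrt(n) * beta * r_i (r_i the correlation of SNP i with the tag: 1 for
the tag, sqrt(within_block_r2) otherwise) and compound-symmetry correlation
sqrt(within_block_r2).  Null blocks have mean zero, so their Z are standard
normal and their p-values uniform.  Effects are reported on the Z scale
(BETA column holds Z, SE = 1).

The secondary table's allele columns are randomly re-oriented per SNP
(swapped, strand-complemented, or both, with the sign negated where the
swap requires it), so the harmonization step is exercised for real: after
correct harmonization the two tables refer to the same effect allele.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .clump import LdReference
from .sumstats import SumStats

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GenomeSpec:
    """Layout of the synthetic LD-block genome."""

    n_chromosomes: int = 2
    blocks_per_chromosome: int = 250
    snps_per_block: int = 8
    within_block_r2: float = 0.5       # genotype r^2 between any two SNPs in a block
    bp_spacing: int = 10_000
    block_gap_bp: int = 600_000        # > clumping window => blocks independent

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.blocks_per_chromosome,
               self.snps_per_block, self.bp_spacing, self.block_gap_bp) <= 0:
            raise ValueError("all genome dimensions must be positive")
        if not (0.0 <= self.within_block_r2 < 1.0):
            raise ValueError("within_block_r2 must be in [0, 1)")

    @property
    def n_blocks(self) -> int:
        return self.n_chromosomes * self.blocks_per_chromosome

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block


@dataclass
class TwoTraitEffectSpec:
    """Causal architecture shared between the two simulated traits.

    pi1/pi2 are per-trait causal-block fractions, pi_shared the fraction
    causal in both; a shared block's signs agree with probability
    p_sign_agree.  effect_sd is the standard deviation of the per-variant
    standardized effect, so a causal tag's expected chi-square is
    1 + n * effect_sd^2.
    """

    pi1: float = 0.1
    pi2: float = 0.1
    pi_shared: float = 0.0
    p_sign_agree: float = 0.5
    effect_sd: float = 0.02
    n1: int = 10_000
    n2: int = 10_000

    def __post_init__(self) -> None:
        if not (0 <= self.pi_shared <= min(self.pi1, self.pi2) + 1e-12):
            raise ValueError("pi_shared must be <= min(pi1, pi2)")
        if not (0.0 <= self.p_sign_agree <= 1.0):
            raise ValueError("p_sign_agree must be in [0, 1]")
        if self.effect_sd < 0 or min(self.n1, self.n2) < 2:
            raise ValueError("effect_sd >= 0 and sample sizes >= 2 required")


@dataclass
class TruthRecord:
    """Ground truth of one simulated pair, for recovery tests."""

    causal_blocks_1: list[str]
    causal_blocks_2: list[str]
    shared_blocks: list[str]
    sign_1: dict[str, int]        # block id -> effect sign in trait 1
    sign_2: dict[str, int]
    tag_snp: dict[str, str]       # block id -> causal tag SNP id
    block_of_snp: dict[str, str]  # SNP id -> block id

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        d["sign_1"] = {k: int(v) for k, v in d["sign_1"].items()}
        d["sign_2"] = {k: int(v) for k, v in d["sign_2"].items()}
        return cls(**d)


@dataclass
class SimulatedPair:
    primary: SumStats
    secondary: SumStats
    ld: LdReference
    truth: TruthRecord
    genome: GenomeSpec
    effects: TwoTraitEffectSpec

    def write_bundle(self, outdir) -> dict[str, Path]:
        """Emit text files in the formats the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "primary": outdir / f"{self.primary.trait_label}.sumstats.txt",
            "secondary": outdir / f"{self.secondary.trait_label}.sumstats.txt",
            "ld": outdir / "ld.txt",
            "truth": outdir / "truth.json",
        }
        self.primary.write(paths["primary"])
        self.secondary.write(paths["secondary"])
        self.ld.write_table(paths["ld"])
        self.truth.write(paths["truth"])
        return paths


def _draw_block_z(rng: np.random.Generator, mean: np.ndarray, corr: float) -> np.ndarray:
    """Compound-symmetry MVN draw: Z = mean + sqrt(c)*u + sqrt(1-c)*e."""
    n_blocks, block_size = mean.shape
    u = rng.standard_normal((n_blocks, 1))
    e = rng.standard_normal((n_blocks, block_size))
    return mean + np.sqrt(corr) * u + np.sqrt(1.0 - corr) * e


def simulate_pair(genome: GenomeSpec | None = None,
                  effects: TwoTraitEffectSpec | None = None,
                  seed: int = 0,
                  trait_labels: tuple[str, str] = ("trait1", "trait2")) -> SimulatedPair:
    """Simulate one pair of summary-statistics tables plus LD and truth.

    All randomness flows from ``seed`` through a single generator.
    """
    genome = genome or GenomeSpec()
    effects = effects or TwoTraitEffectSpec()
    rng = np.random.default_rng(seed)

    B, S = genome.n_blocks, genome.snps_per_block
    corr = float(np.sqrt(genome.within_block_r2))  # Z-score correlation within block

    # block layout
    block_ids, snp_ids, chroms, bps = [], [], [], []
    for c in range(1, genome.n_chromosomes + 1):
        pos = 1
        for b in range(genome.blocks_per_chromosome):
            bid = f"c{c}b{b}"
            block_ids.append(bid)
            for k in range(S):
                snp_ids.append(f"rs_{bid}_{k}")
                chroms.append(str(c))
                bps.append(pos)
                pos += genome.bp_spacing
            pos += genome.block_gap_bp
    snp_ids = np.array(snp_ids)
    chroms = np.array(chroms)
    bps = np.array(bps, dtype=np.int64)

    # causal architecture: shared / only-1 / only-2 / null per block
    u = rng.random(B)
    p_shared = effects.pi_shared
    p_only1 = effects.pi1 - effects.pi_shared
    p_only2 = effects.pi2 - effects.pi_shared
    shared = u < p_shared
    only1 = (u >= p_shared) & (u < p_shared + p_only1)
    only2 = (u >= p_shared + p_only1) & (u < p_shared + p_only1 + p_only2)
    causal1 = shared | only1
    causal2 = shared | only2

    sign1 = rng.choice([-1, 1], size=B)
    agree = rng.random(B) < effects.p_sign_agree
    sign2 = np.where(shared, np.where(agree, sign1, -sign1),
                     rng.choice([-1, 1], size=B))

    mag1 = np.abs(rng.normal(0.0, effects.effect_sd, size=B))
    mag2 = np.abs(rng.normal(0.0, effects.effect_sd, size=B))
    beta1 = np.where(causal1, sign1 * mag1, 0.0)
    beta2 = np.where(causal2, sign2 * mag2, 0.0)

    # tag is the first SNP of each block; mean Z profile follows LD with the tag
    r_profile = np.full(S, corr)
    r_profile[0] = 1.0
    mean1 = np.sqrt(effects.n1) * beta1[:, None] * r_profile[None, :]
    mean2 = np.sqrt(effects.n2) * beta2[:, None] * r_profile[None, :]

    z1 = _draw_block_z(rng, mean1, corr).ravel()
    z2 = _draw_block_z(rng, mean2, corr).ravel()
    p1 = np.clip(2.0 * stats.norm.sf(np.abs(z1)), 1e-300, 1.0)
    p2 = np.clip(2.0 * stats.norm.sf(np.abs(z2)), 1e-300, 1.0)

    # alleles: non-palindromic pairs; secondary re-oriented at random
    n = genome.n_snps
    pair_idx = rng.integers(0, len(_NONPALINDROMIC), size=n)
    a1 = np.array([_NONPALINDROMIC[i][0] for i in pair_idx])
    a2 = np.array([_NONPALINDROMIC[i][1] for i in pair_idx])
    eaf = rng.uniform(0.05, 0.95, size=n)

    orient = rng.integers(0, 4, size=n)  # 0 same, 1 swapped, 2 complement, 3 both
    comp = np.vectorize(_COMPLEMENT.get)
    a1_sec = np.select(
        [orient == 0, orient == 1, orient == 2, orient == 3],
        [a1, a2, comp(a1), comp(a2)], default="N")
    a2_sec = np.select(
        [orient == 0, orient == 1, orient == 2, orient == 3],
        [a2, a1, comp(a2), comp(a1)], default="N")
    swap = (orient == 1) | (orient == 3)
    z2_reported = np.where(swap, -z2, z2)
    eaf_sec = np.where(swap, 1.0 - eaf, eaf)

    def table(label, a1_, a2_, eaf_, z, p) -> SumStats:
        df = pd.DataFrame({
            "snp": snp_ids, "chr": chroms, "bp": bps,
            "a1": a1_, "a2": a2_, "eaf": eaf_,
            "beta": z, "se": 1.0, "p": p,
        }).sort_values(["chr", "bp"], kind="mergesort").reset_index(drop=True)
        return SumStats(trait_label=label, df=df, effect_scale="z")

    primary = table(trait_labels[0], a1, a2, eaf, z1, p1)
    secondary = table(trait_labels[1], a1_sec, a2_sec, eaf_sec, z2_reported, p2)

    ld = LdReference()
    for b in range(B):
        ids = snp_ids[b * S:(b + 1) * S]
        for i in range(S):
            for j in range(i + 1, S):
                ld.add(ids[i], ids[j], genome.within_block_r2)

    block_arr = np.array(block_ids)
    truth = TruthRecord(
        causal_blocks_1=sorted(block_arr[causal1].tolist()),
        causal_blocks_2=sorted(block_arr[causal2].tolist()),
        shared_blocks=sorted(block_arr[shared].tolist()),
        sign_1={bid: int(s) for bid, s, c in zip(block_ids, sign1, causal1) if c},
        sign_2={bid: int(s) for bid, s, c in zip(block_ids, sign2, causal2) if c},
        tag_snp={bid: f"rs_{bid}_0" for bid, c in zip(block_ids, causal1 | causal2) if c},
        block_of_snp={sid: sid.split("_")[1] for sid in snp_ids},
    )
    return SimulatedPair(primary=primary, secondary=secondary, ld=ld, truth=truth,
                         genome=genome, effects=effects)


#: named fixtures used throughout the test suite and docs
FIXTURES: dict[str, TwoTraitEffectSpec] = {
    "null_pair": TwoTraitEffectSpec(pi1=0.1, pi2=0.1, pi_shared=0.0),
    "concordant_pair": TwoTraitEffectSpec(pi1=0.35, pi2=0.35, pi_shared=0.3,
                                          p_sign_agree=1.0),
    "discordant_pair": TwoTraitEffectSpec(pi1=0.35, pi2=0.35, pi_shared=0.3,
                                          p_sign_agree=0.0),
    "pleiotropy_no_concordance": TwoTraitEffectSpec(pi1=0.35, pi2=0.35, pi_shared=0.3,
                                                    p_sign_agree=0.5),
    "cfdr_enriched": TwoTraitEffectSpec(pi1=0.25, pi2=0.25, pi_shared=0.2,
                                        p_sign_agree=1.0, effect_sd=0.032),
}


def make_fixture(name: str, seed: int = 0,
                 genome: GenomeSpec | None = None) -> SimulatedPair:
    """Seeded named scenario bundles exercising specific overlap regimes."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return simulate_pair(genome=genome, effects=FIXTURES[name], seed=seed)
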