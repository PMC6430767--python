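"""End-to-end orchestration for one primary trait against many conditioning traits.

Runs harmonize -> clump (ranked on each conditioning trait) -> SECA
permutation tests -> conditional FDR -> stratified TDR for every
(primary, secondary) pair, applies the Bonferroni policy across traits,
volumes and methods, and writes all result tables plus a machine-readable
run log.  Outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cfdr import DEFAULT_LEVELS, DEFAULT_STRATA, bh_qvalues, conditional_fdr, stratified_tdr
from .clump import ClumpConfig, LdReference, clump
from .seca import ThresholdGrid, run_seca
from .sumstats import SumStats, read_sumstats

logger = logging.getLogger(__name__)


def bonferroni_threshold(n_traits: int, n_volumes: int, n_methods: int = 2) -> float:
    """Family-wise 5% threshold over traits x conditioning phenotypes x methods."""
    if min(n_traits, n_volumes, n_methods) < 1:
        raise ValueError("all counts must be >= 1")
    return 0.05 / (n_traits * n_volumes * n_methods)


def annotate_significance(p: float, bonferroni: float) -> str:
    """Three-band annotation: significant / nominal / trending / ns."""
    if p <= bonferroni:
        return "significant"
    if p < 0.05:
        return "nominal"
    if p < 0.1:
        return "trending"
    return "ns"


@dataclass
class TraitInput:
    label: str
    path: str
    column_map: dict | None = None
    effect_scale: str = "beta"
    n_samples: int | None = None  # enables % variance explained in outputs


@dataclass
class RunConfig:
    primary: TraitInput
    secondaries: list[TraitInput]
    ld_path: str
    outdir: str = "crosstrait_out"
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    n_perm: int = 9999
    seed: int = 0
    cfdr_levels: tuple[float, ...] = DEFAULT_LEVELS
    cfdr_alpha: float = 0.05
    tdr_strata: tuple[float, ...] = DEFAULT_STRATA
    drop_palindromic: bool = True
    n_tests_bonferroni: int | None = None  # default: n_primary x n_secondary x 2
    write_grids: bool = False

    def __post_init__(self) -> None:
        if not self.secondaries:
            raise ValueError("at least one secondary trait is required")

    @property
    def bonferroni(self) -> float:
        n_tests = self.n_tests_bonferroni or (1 * len(self.secondaries) * 2)
        if n_tests < 1:
            raise ValueError("n_tests_bonferroni must be >= 1")
        return 0.05 / n_tests

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        primary = TraitInput(**raw["primary"])
        secondaries = [TraitInput(**s) for s in raw["secondaries"]]
        kwargs = {k: v for k, v in raw.items() if k not in ("primary", "secondaries", "clump", "grid")}
        if "clump" in raw:
            kwargs["clump"] = ClumpConfig(**raw["clump"])
        if "grid" in raw:
            kwargs["grid"] = ThresholdGrid(**raw["grid"])
        return cls(primary=primary, secondaries=secondaries, **kwargs)


@dataclass
class RunReport:
    seca_table: pd.DataFrame
    discoveries: pd.DataFrame
    bonferroni_threshold: float
    outdir: Path
    failures: dict[str, str]


def _load(trait: TraitInput) -> SumStats:
    return read_sumstats(trait.path, column_map=trait.column_map,
                         effect_scale=trait.effect_scale, trait_label=trait.label)


def run_all(config: RunConfig) -> RunReport:
    """Execute the full analysis for every (primary, secondary) pair.

    Per-pair failures are isolated: the pair is recorded in the run log and
    the run continues.  All output tables land under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    primary = _load(config.primary)
    ld = LdReference.read_table(config.ld_path)
    bonf = config.bonferroni

    # independent child seeds per pair, derived deterministically from the root
    child_seeds = [int(s.generate_state(1)[0] % (2**31))
                   for s in np.random.SeedSequence(config.seed).spawn(len(config.secondaries))]

    seca_rows, discovery_frames, failures = [], [], {}
    for sec_input, pair_seed in zip(config.secondaries, child_seeds):
        try:
            secondary = _load(sec_input)
            result = run_seca(primary, secondary, ld,
                              clump_config=config.clump, grid=config.grid,
                              n_perm=config.n_perm, seed=pair_seed,
                              drop_palindromic=config.drop_palindromic)
            row = result.row()
            row["annotation_pleiotropy"] = annotate_significance(row["p_pleiotropy"], bonf)
            row["annotation_concordance"] = annotate_significance(row["p_concordance"], bonf)
            seca_rows.append(row)

            idx = result.index_variants
            q_conditioning = bh_qvalues(idx["p2"].to_numpy())
            cfdr = conditional_fdr(idx["p1"].to_numpy(), q_conditioning,
                                   levels=config.cfdr_levels, alpha=config.cfdr_alpha,
                                   snp_ids=idx["snp"].to_numpy())
            cfdr_df = cfdr.df.merge(idx[["snp", "chr", "bp"]], on="snp")
            cfdr_df.insert(0, "conditioning_trait", sec_input.label)
            # results-table columns: alleles, both traits' effects, % variance
            prim_cols = primary.df[["snp", "a1", "a2", "eaf", "beta", "se", "p"]].rename(
                columns={"a1": "ea", "a2": "nea", "eaf": "freq",
                         "beta": "effect_primary", "se": "se_primary", "p": "p_primary_raw"})
            sec_cols = secondary.df[["snp", "beta", "se", "p"]].rename(
                columns={"beta": "effect_secondary", "se": "se_secondary",
                         "p": "p_secondary"})
            cfdr_df = cfdr_df.merge(prim_cols, on="snp").merge(sec_cols, on="snp")
            cfdr_df = cfdr_df.drop(columns=["p_primary_raw"])
            # re-sign the secondary effect onto the primary's effect allele
            sign2 = cfdr_df.merge(idx[["snp", "sign2"]], on="snp")["sign2"]
            cfdr_df["effect_secondary"] = sign2.to_numpy() * cfdr_df["effect_secondary"].abs()
            if config.primary.n_samples is not None:
                from .cfdr import variance_explained
                cfdr_df["pct_var_primary"] = [
                    variance_explained(b, s, config.primary.n_samples)
                    if np.isfinite(s) and s > 0 else np.nan
                    for b, s in zip(cfdr_df["effect_primary"], cfdr_df["se_primary"])]
            cfdr_df.to_csv(outdir / f"cfdr_{sec_input.label}.tsv", sep="\t",
                           index=False, float_format="%.6g")
            disc = cfdr_df[cfdr_df["significant"]]
            if not disc.empty:
                discovery_frames.append(disc)

            curves = stratified_tdr(idx["p1"].to_numpy(), idx["p2"].to_numpy(),
                                    strata=config.tdr_strata)
            if curves:
                pd.concat([c.as_frame() for c in curves]).to_csv(
                    outdir / f"tdr_{sec_input.label}.tsv", sep="\t",
                    index=False, float_format="%.6g")
            if config.write_grids:
                result.pleiotropy_cells.to_csv(
                    outdir / f"grid_pleiotropy_{sec_input.label}.tsv",
                    sep="\t", index=False, float_format="%.6g")
                result.concordance_cells.to_csv(
                    outdir / f"grid_concordance_{sec_input.label}.tsv",
                    sep="\t", index=False, float_format="%.6g")
        except Exception as exc:  # per-pair isolation
            logger.exception("pair (%s, %s) failed", config.primary.label, sec_input.label)
            failures[sec_input.label] = str(exc)

    seca_table = pd.DataFrame(seca_rows)
    seca_table.to_csv(outdir / "seca_results.tsv", sep="\t", index=False,
                      float_format="%.6g")
    discoveries = (pd.concat(discovery_frames, ignore_index=True)
                   if discovery_frames else pd.DataFrame())
    discoveries.to_csv(outdir / "conditional_discoveries.tsv", sep="\t",
                       index=False, float_format="%.6g")

    log = {
        "version": __version__,
        "seed": config.seed,
        "pair_seeds": dict(zip([s.label for s in config.secondaries], child_seeds)),
        "n_perm": config.n_perm,
        "bonferroni_threshold": bonf,
        "clump": asdict(config.clump),
        "cfdr_levels": list(config.cfdr_levels),
        "tdr_strata": list(config.tdr_strata),
        "failures": failures,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)

    return RunReport(seca_table=seca_table, discoveries=discoveries,
                     bonferroni_threshold=bonf, outdir=outdir, failures=failures)
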