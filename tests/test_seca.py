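"""Grid-based pleiotropy/concordance tests and their permutation summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crosstrait import (
    ThresholdGrid,
    concordance_grid,
    make_fixture,
    permutation_summary,
    pleiotropy_grid,
    run_seca,
)


def hypergeom_tail_enum(k, N, K, d):
    """P(X >= k) for X ~ Hypergeom(N, K, d), by explicit support enumeration."""
    total = 0.0
    for m in range(max(0, K + d - N), min(K, d) + 1):
        if m >= k:
            total += (math.comb(K, m) * math.comb(N - K, d - m)) / math.comb(N, d)
    return total


def binom_tail_enum(k, n):
    """P(#concordant >= k) under fair signs, by enumerating all 2^n outcomes."""
    return sum(1 for bits in itertools.product([0, 1], repeat=n)
               if sum(bits) >= k) / 2 ** n


def variants_frame(p1, p2, sign1=None, sign2=None):
    n = len(p1)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n)],
        "chr": "1",
        "bp": np.arange(n) + 1,
        "p1": p1,
        "sign1": sign1 if sign1 is not None else np.ones(n, dtype=int),
        "p2": p2,
        "sign2": sign2 if sign2 is not None else np.ones(n, dtype=int),
    })


SMALL_GRID = ThresholdGrid((0.05, 0.5, 1.0), (0.05, 0.5, 1.0))


class TestPleiotropyGrid:
    def test_degenerate_all_p_one(self):
        df = variants_frame(np.ones(20), np.ones(20))
        cells = pleiotropy_grid(df, SMALL_GRID)
        full = cells[(cells.t1 == 1.0) & (cells.t2 == 1.0)].iloc[0]
        assert full.n_both == 20
        sub = cells[(cells.t1 < 1.0) | (cells.t2 < 1.0)]
        assert (sub.n_both == 0).all()
        assert (sub.enrichment_p == 1.0).all()

    def test_enrichment_matches_hypergeometric_enumeration(self):
        # counts both=5, only1=5, only2=5, neither=85 at the (0.05, 0.05) cell
        p1 = np.r_[np.full(10, 0.01), np.full(90, 0.9)]
        p2 = np.r_[np.full(5, 0.01), np.full(5, 0.9), np.full(5, 0.01), np.full(85, 0.9)]
        df = variants_frame(p1, p2)
        cells = pleiotropy_grid(df, SMALL_GRID)
        cell = cells[(cells.t1 == 0.05) & (cells.t2 == 0.05)].iloc[0]
        assert (cell.n_both, cell.n_only1, cell.n_only2, cell.n_neither) == (5, 5, 5, 85)
        assert cell.enrichment_p == pytest.approx(hypergeom_tail_enum(5, 100, 10, 10))

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(2)
        df = variants_frame(rng.uniform(size=50), rng.uniform(size=50))
        cells = pleiotropy_grid(df)
        assert (cells[["n_both", "n_only1", "n_only2", "n_neither"]].sum(axis=1) == 50).all()

    def test_null_cell_rejection_rate_near_alpha(self):
        # p2 a random permutation of p1: cell tests should be ~calibrated
        rng = np.random.default_rng(7)
        hits = total = 0
        for _ in range(300):
            p1 = rng.uniform(size=200)
            p2 = rng.permutation(p1)
            cells = pleiotropy_grid(variants_frame(p1, p2), SMALL_GRID)
            proper = cells[(cells.t1 < 1.0) & (cells.t2 < 1.0)]
            hits += (proper.enrichment_p <= 0.05).sum()
            total += len(proper)
        rate = hits / total
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)


class TestConcordanceGrid:
    def test_matches_exhaustive_enumeration(self):
        # 10 SNPs in the tight cell, 8 concordant -> p = 56/1024
        sign2 = np.r_[np.ones(8), -np.ones(2)].astype(int)
        df = variants_frame(np.full(10, 0.01), np.full(10, 0.01), sign2=sign2)
        cells = concordance_grid(df, SMALL_GRID)
        cell = cells[(cells.t1 == 0.05) & (cells.t2 == 0.05)].iloc[0]
        assert cell.n_concordant == 8 and cell.n_discordant == 2
        assert cell.concordance_p_excess == pytest.approx(56 / 1024)
        assert cell.concordance_p_excess == pytest.approx(binom_tail_enum(8, 10))
        assert cell.concordance_p_deficit == pytest.approx(1 - binom_tail_enum(9, 10))

    def test_single_concordant_snp(self):
        df = variants_frame([0.01], [0.01])
        cell = concordance_grid(df, SMALL_GRID).iloc[0]
        assert cell.concordance_p_excess == pytest.approx(0.5)

    def test_empty_cell_noninformative(self):
        df = variants_frame([0.9], [0.9])
        cells = concordance_grid(df, SMALL_GRID)
        empty = cells[(cells.t1 == 0.05) & (cells.t2 == 0.05)].iloc[0]
        assert empty.n_both == 0
        assert empty.concordance_p_excess == 1.0
        assert empty.concordance_p_deficit == 1.0


class TestPermutationSummary:
    def test_degenerate_null_gives_p_one(self):
        # all p2 = 1: every permutation leaves the grid unchanged
        df = variants_frame(np.linspace(0.01, 1, 20), np.ones(20))
        s = permutation_summary(df, mode="pleiotropy", n_perm=99, seed=0)
        assert s.empirical_p == 1.0

    def test_add_one_rule_floor(self):
        pair = make_fixture("concordant_pair", seed=0)
        from crosstrait import clump, harmonize
        idx = clump(harmonize(pair.primary, pair.secondary), pair.ld).index_df
        s = permutation_summary(idx, mode="concordance", n_perm=99, seed=1)
        assert s.empirical_p >= 1 / 100

    def test_deterministic_given_seed(self, harmonized_small):
        a = permutation_summary(harmonized_small, mode="concordance", n_perm=99, seed=11)
        b = permutation_summary(harmonized_small, mode="concordance", n_perm=99, seed=11)
        assert a == b

    def test_sign_flip_swaps_direction_not_pleiotropy(self):
        pair = make_fixture("concordant_pair", seed=3)
        from crosstrait import clump, harmonize
        idx = clump(harmonize(pair.primary, pair.secondary), pair.ld).index_df
        flipped = idx.copy()
        flipped["sign2"] = -flipped["sign2"]
        conc = permutation_summary(idx, mode="concordance", n_perm=99, seed=5)
        conc_f = permutation_summary(flipped, mode="concordance", n_perm=99, seed=5)
        assert {conc.direction, conc_f.direction} == {"+", "-"}
        pleio = permutation_summary(idx, mode="pleiotropy", n_perm=99, seed=5)
        pleio_f = permutation_summary(flipped, mode="pleiotropy", n_perm=99, seed=5)
        assert pleio.empirical_p == pleio_f.empirical_p

    def test_count_summary_available(self, harmonized_small):
        s = permutation_summary(harmonized_small, mode="pleiotropy", n_perm=49,
                                seed=2, summary="count")
        assert 0 < s.empirical_p <= 1

    def test_ci_brackets_empirical_p(self, harmonized_small):
        s = permutation_summary(harmonized_small, mode="pleiotropy", n_perm=99, seed=4)
        assert s.ci_low <= s.empirical_p <= s.ci_high


class TestRunSeca:
    def test_self_comparison_is_maximally_significant(self):
        pair = make_fixture("null_pair", seed=9)
        res = run_seca(pair.primary, pair.primary, pair.ld, n_perm=99, seed=0)
        assert res.pleiotropy.empirical_p == pytest.approx(1 / 100)
        assert res.concordance.empirical_p == pytest.approx(1 / 100)
        assert res.concordance.direction == "+"

    def test_concordant_fixture_recovered(self):
        pair = make_fixture("concordant_pair", seed=21)
        res = run_seca(pair.primary, pair.secondary, pair.ld, n_perm=199, seed=1)
        assert res.concordance.empirical_p <= 0.05
        assert res.concordance.direction == "+"

    def test_discordant_fixture_recovered(self):
        pair = make_fixture("discordant_pair", seed=22)
        res = run_seca(pair.primary, pair.secondary, pair.ld, n_perm=199, seed=1)
        assert res.concordance.empirical_p <= 0.05
        assert res.concordance.direction == "-"

    def test_row_schema(self):
        pair = make_fixture("null_pair", seed=2)
        res = run_seca(pair.primary, pair.secondary, pair.ld, n_perm=49, seed=0)
        row = res.row()
        assert set(row) >= {"trait1", "trait2", "p_pleiotropy", "p_concordance",
                            "direction", "ci_pleiotropy_low", "ci_concordance_high"}


class TestThresholdGrid:
    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            ThresholdGrid((0.5, 0.1, 1.0))
        with pytest.raises(ValueError):
            ThresholdGrid((0.1, 0.5))  # must end at 1
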