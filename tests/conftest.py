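import numpy as np
import pandas as pd
import pytest

from crosstrait import SumStats


def make_table(rows, label="trait", effect_scale="beta") -> SumStats:
    """Build a SumStats from (snp, chr, bp, a1, a2, beta, p) tuples."""
    df = pd.DataFrame(rows, columns=["snp", "chr", "bp", "a1", "a2", "beta", "p"])
    df["eaf"] = np.nan
    df["se"] = np.nan
    df = df.sort_values(["chr", "bp"], kind="mergesort").reset_index(drop=True)
    return SumStats(trait_label=label, df=df, effect_scale=effect_scale)


@pytest.fixture
def sumstats_file(tmp_path):
    """Write a 3-row default-column summary-statistics file; return its path."""
    path = tmp_path / "trait.txt"
    path.write_text(
        "SNP\tCHR\tBP\tA1\tA2\tFRQ\tBETA\tSE\tP\n"
        "rs1\t1\t1000\tA\tG\t0.3\t0.10\t0.02\t0.001\n"
        "rs2\t1\t2000\tC\tT\t0.5\t-0.20\t0.05\t0.04\n"
        "rs3\t2\t500\tG\tA\t0.7\t0.00\t0.01\t0.9\n"
    )
    return path


@pytest.fixture
def harmonized_small():
    """Five harmonized SNPs with hand-set p-values and signs."""
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(1, 6)],
        "chr": ["1"] * 5,
        "bp": [1_000, 100_000, 200_000, 700_000, 800_000],
        "p1": [0.5, 0.2, 0.9, 0.01, 0.3],
        "sign1": [1, -1, 1, 1, -1],
        "p2": [0.001, 0.01, 0.02, 0.005, 0.5],
        "sign2": [1, 1, -1, 1, 1],
    })
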