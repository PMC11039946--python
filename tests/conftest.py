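import numpy as np
import pandas as pd
import pytest

from mrkit import HarmonizedDataset, LdMatrix, SummaryStatistics


def make_sumstats_frame(rows):
    """Build a canonical summary-statistics frame from compact row tuples:
    (snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n)."""
    cols = [
        "snp_id", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "pval", "n",
    ]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def toy_sumstats():
    df = make_sumstats_frame(
        [
            ("rs1", "1", 1_000_000, "A", "G", 0.30, 0.10, 0.010, 1e-23, 50_000),
            ("rs2", "2", 2_000_000, "C", "T", 0.20, -0.08, 0.012, 3e-11, 50_000),
            ("rs3", "3", 3_000_000, "G", "C", 0.45, 0.06, 0.011, 5e-8, 50_000),
            ("rs4", "4", 4_000_000, "T", "C", 0.10, 0.05, 0.013, 1e-4, 50_000),
        ]
    )
    return SummaryStatistics(trait_name="toy", records=df)


@pytest.fixture
def toy_harmonized():
    """5 strong instruments with a true slope near 0.3 and mild noise."""
    beta_exp = np.array([0.10, 0.08, 0.12, 0.09, 0.11])
    se_exp = np.full(5, 0.005)
    beta_out = np.array([0.031, 0.022, 0.038, 0.026, 0.035])
    se_out = np.array([0.010, 0.012, 0.011, 0.009, 0.010])
    return HarmonizedDataset.from_arrays(beta_exp, se_exp, beta_out, se_out)


@pytest.fixture
def identity_ld():
    def _make(snp_ids):
        return LdMatrix.identity(snp_ids)

    return _make
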