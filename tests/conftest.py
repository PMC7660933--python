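import numpy as np
import pandas as pd
import pytest

from cdmr import LDMatrix, SummaryStatsTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def make_stats(
    snp_ids, beta, se, n=10_000, eaf=0.3, pval=1e-10, chrom="1", pos=None, trait=""
):
    m = len(snp_ids)
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "effect_allele": "A",
            "other_allele": "G",
            "beta": beta,
            "se": se,
            "n": n,
            "eaf": eaf,
            "pval": pval,
        }
    )
    return SummaryStatsTable(df, trait=trait)


@pytest.fixture
def identity_ld():
    def _make(m):
        return LDMatrix([f"s{i}" for i in range(m)], np.eye(m))

    return _make
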