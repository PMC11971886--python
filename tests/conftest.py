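import numpy as np
import pandas as pd
import pytest

from cismr.sumstats import CASE_CONTROL, COLUMNS, QUANTITATIVE, SumStats


def make_sumstats(records, trait_id="trait", trait_type=QUANTITATIVE, **kw):
    """Build a SumStats from a list of per-SNP dicts, filling sane defaults."""
    rows = []
    for i, rec in enumerate(records):
        row = {
            "snp_id": f"rs{i + 1}",
            "chrom": "1",
            "pos": 1000 + i * 1000,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            "beta": 0.1,
            "se": 0.02,
            "pval": 5.7e-7,
            "n": 10_000,
        }
        row.update(rec)
        rows.append(row)
    df = pd.DataFrame(rows)[COLUMNS]
    if trait_type == CASE_CONTROL:
        kw.setdefault("n_case", 10_000)
        kw.setdefault("n_control", 100_000)
    return SumStats(trait_id, trait_type, df, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
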