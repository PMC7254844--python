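import numpy as np
import pandas as pd
import pytest

from progbias.pipeline import generate_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Shared small deterministic dataset bundle (cohort, sumstats pair, LD panel)."""
    return generate_fixtures(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_sumstats(
    n=5,
    chrom=1,
    bp_start=1_000,
    bp_step=10_000,
    ea="A",
    oa="G",
    seed=0,
    p=None,
):
    """Hand-rollable summary-statistics table for format-level tests."""
    r = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n)],
            "CHR": chrom,
            "BP": bp_start + bp_step * np.arange(n),
            "EA": ea,
            "OA": oa,
            "EAF": r.uniform(0.05, 0.95, n).round(3),
            "BETA": r.normal(0, 0.1, n).round(4),
            "SE": r.uniform(0.01, 0.05, n).round(4),
            "P": p if p is not None else r.uniform(1e-6, 0.9, n),
            "INFO": 1.0,
        }
    )
    return df
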