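import numpy as np
import pandas as pd
import pytest

from rnasizebias import (
    Biotype,
    ExpressionMatrix,
    RAW_COUNTS,
    TPM,
    TranscriptRecord,
    TranscriptSizeTable,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20231116)


@pytest.fixture
def small_table():
    """Five genes spanning short to long transcripts."""
    df = pd.DataFrame(
        {
            "length_bp": [200, 550, 1000, 5000, 30000],
            "biotype": ["mRNA", "lncRNA", "mRNA", "mRNA", "mRNA"],
        },
        index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene_id"),
    )
    return TranscriptSizeTable(df, source_label="fixture")


@pytest.fixture
def random_table(rng):
    """100-gene table with random lengths and biotypes."""
    n = 100
    lengths = rng.integers(180, 43_816, n)
    biotypes = rng.choice(["mRNA", "lncRNA", "other"], n, p=[0.7, 0.25, 0.05])
    df = pd.DataFrame(
        {"length_bp": lengths, "biotype": biotypes},
        index=pd.Index([f"g{i:03d}" for i in range(n)], name="gene_id"),
    )
    return TranscriptSizeTable(df)


def make_matrix(values, unit=RAW_COUNTS, genes=None, samples=None, label="test"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), unit=unit, dataset_label=label
    )


@pytest.fixture
def count_matrix(rng, random_table):
    """Random 100-gene x 4-sample count matrix aligned to random_table."""
    counts = rng.poisson(50, (100, 4)).astype(float)
    return ExpressionMatrix(
        pd.DataFrame(
            counts, index=random_table.gene_ids, columns=["s1", "s2", "s3", "s4"]
        ),
        unit=RAW_COUNTS,
        dataset_label="random",
    )
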