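import numpy as np
import pandas as pd
import pytest

from digitexpr import (
    CountMatrix,
    TranscriptLengthTable,
    conserved_module_config,
    simulate_counts,
)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """2 genes x 4 samples, one species, 2 digits x 2 replicates."""
    counts = pd.DataFrame(
        [[10, 12, 40, 44], [5, 7, 6, 4]],
        index=["gA", "gB"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "species": "mouse",
            "limb": "fore",
            "digit": [1, 1, 2, 2],
            "stage": "e13",
            "replicate": [1, 2, 1, 2],
        }
    ).set_index("sample_id")
    return CountMatrix(counts, meta)


@pytest.fixture
def tiny_lengths() -> TranscriptLengthTable:
    return TranscriptLengthTable(pd.Series({"gA": 1000.0, "gB": 500.0}))


@pytest.fixture(scope="session")
def module_sim():
    """One small conserved-D1-module simulation shared across tests."""
    return simulate_counts(conserved_module_config(seed=11, n_orthologs=400))



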