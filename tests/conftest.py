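import numpy as np
import pandas as pd
import pytest

from cnvfactor import CountMatrix, SampleTable, TargetSet, generate_null


@pytest.fixture(scope="session")
def small_cohort():
    """A small CNV-free cohort drawn from the background model."""
    return generate_null(n=300, m=30, K=2, seed=42)


@pytest.fixture
def toy_targets():
    return TargetSet(
        pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [100, 700, 1500],
                "end": [600, 1200, 1900],
                "gc": [45.0, 52.0, 38.0],
                "mappability": [0.99, 0.97, 1.0],
                "gene": ["gA", "gA", "gB"],
            }
        )
    )


@pytest.fixture
def toy_samples():
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "role": ["control", "case"],
                "batch": ["b1", "b1"],
            }
        )
    )


@pytest.fixture
def toy_counts(toy_targets, toy_samples):
    vals = np.array([[100, 120], [80, 90], [200, 210]])
    return CountMatrix(vals, toy_targets, toy_samples)
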