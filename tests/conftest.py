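import numpy as np
import pandas as pd
import pytest

from platelet_landscape.io_tables import CountMatrix
from platelet_landscape.preprocess import NormalizedMatrix
from platelet_landscape.synthetic_cohort import ClusterBlock, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact generated cohort shared by read-only tests.

    The planted cluster block is scaled to the gene count so it keeps the
    same minority share of the transcriptome as at full cohort size.
    """
    return generate_cohort(
        CohortConfig(
            n_samples=50,
            n_female=26,
            n_genes_retained_target=300,
            n_genes_low=40,
            cluster_block=ClusterBlock(n_genes=20, n_extreme=2),
            seed=11,
        )
    )


@pytest.fixture
def toy_counts() -> CountMatrix:
    counts = np.array(
        [
            [10, 20, 30],
            [100, 200, 300],
            [0, 5, 10],
            [7, 7, 7],
        ]
    )
    return CountMatrix(["g1", "g2", "g3", "g4"], ["s1", "s2", "s3"], counts)


@pytest.fixture
def toy_norm() -> NormalizedMatrix:
    values = np.log2(
        np.array(
            [
                [16.0, 16.0, 64.0, 64.0],
                [32.0, 32.0, 32.0, 32.0],
                [4.0, 8.0, 4.0, 8.0],
            ]
        )
        + 1.0
    )
    return NormalizedMatrix(
        ["gA", "gB", "gC"], ["s1", "s2", "s3", "s4"], values, np.ones(4)
    )


@pytest.fixture
def toy_groups() -> pd.Series:
    return pd.Series(
        {"s1": "one", "s2": "one", "s3": "two", "s4": "two"}, name="group"
    )
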