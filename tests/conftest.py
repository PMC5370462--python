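import numpy as np
import pandas as pd
import pytest

from dmrscan import synthetic_data as sd
from dmrscan.meth_io import MethCallTable


def make_table(records, sample_id="s1", cohort=None):
    """records: iterable of (chrom, pos, strand, n_meth, n_unmeth)."""
    df = pd.DataFrame(
        records, columns=["chrom", "pos", "strand", "n_meth", "n_unmeth"]
    )
    return MethCallTable(sample_id=sample_id, data=df, cohort=cohort)


@pytest.fixture
def strand_table():
    return make_table(
        [
            ("chr1", 100, "+", 5, 3),
            ("chr1", 101, "-", 2, 4),
            ("chr1", 200, "+", 1, 1),
            ("chr1", 301, "-", 2, 4),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small planted genome with young/old WT cohorts (shared across tests)."""
    cfg = sd.SimConfig(
        seed=7,
        chrom_lengths={"chr1": 1_000_000},
        n_genes=25,
        n_enhancers=40,
        n_islands=8,
        n_super_enhancers=5,
    )
    genome = sd.build_genome(cfg)
    young = sd.simulate_cohort(genome, "WTY", age="young", rng=71)
    old = sd.simulate_cohort(genome, "WTO", age="old", rng=72)
    return genome, young, old
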