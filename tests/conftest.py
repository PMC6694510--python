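import numpy as np
import pandas as pd
import pytest

from f2mosaic.pedigree import GenomeSpec
from f2mosaic.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return GenomeSpec([("chr1", 20_000_000), ("chr2", 10_000_000)])


@pytest.fixture(scope="session")
def toy_dataset(small_genome):
    """Two-family cohort on a 30-Mb genome at study-default densities."""
    cfg = SimConfig(genome=small_genome, n_families=2, seed=1)
    return simulate_dataset(cfg)


@pytest.fixture()
def minimal_pedigree() -> pd.DataFrame:
    rows = [
        ("H1", "F0", "H", "NA", "NA"),
        ("H2", "F0", "H", "NA", "NA"),
        ("L1", "F0", "L", "NA", "NA"),
        ("L2", "F0", "L", "NA", "NA"),
        ("S1", "F1", "NA", "H1", "L1"),
        ("D1", "F1", "NA", "H2", "L2"),
        ("X1", "F2", "NA", "S1", "D1"),
    ]
    return pd.DataFrame(rows, columns=["id", "generation", "line", "sire", "dam"])
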