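import numpy as np
import pandas as pd
import pytest

from dmrcall import SimulationParams, generate_dataset


def count_table(rows):
    """Build a count table from (chrom, pos, n_meth, n_unmeth) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_unmeth"])


@pytest.fixture
def four_sample_tables():
    """Two control + two heat samples over three shared CpGs plus strays."""
    tables = {
        "s_ctrl_1": count_table([("chr1", 100, 3, 7), ("chr1", 150, 2, 3),
                                 ("chr1", 300, 5, 5)]),
        "s_ctrl_2": count_table([("chr1", 100, 2, 8), ("chr1", 150, 1, 4),
                                 ("chr1", 300, 4, 2)]),
        "s_heat_1": count_table([("chr1", 100, 9, 1), ("chr1", 150, 4, 1),
                                 ("chr1", 300, 3, 3)]),
        "s_heat_2": count_table([("chr1", 100, 8, 2), ("chr1", 150, 3, 2),
                                 ("chr1", 300, 2, 4), ("chr2", 10, 6, 6)]),
    }
    design = pd.DataFrame({
        "sample_id": list(tables),
        "father_group": ["F"] * 4,
        "arm": ["control", "control", "heat", "heat"],
        "organ": ["liver"] * 4,
        "pooled": [False] * 4,
    })
    return tables, design


def small_sim_params(**overrides):
    """A down-scaled simulated study that still exercises every stage."""
    defaults = dict(n_chroms=1, chrom_length=300_000, n_genes_per_chrom=4,
                    n_islands_per_chrom=5, n_planted_dmrs=3,
                    coverage_mean=20.0, planted_effect=0.5, seed=11)
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_sim_params())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
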