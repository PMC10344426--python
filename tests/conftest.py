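import numpy as np
import pandas as pd
import pytest

from finemark.genome import GenomeLayout, make_intervals
from finemark.synth import SimulationConfig


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 600_000})


@pytest.fixture
def tiny_layout():
    return GenomeLayout({"chrT": 10_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_intervals(rng, layout):
    """~100 random valid intervals across both chromosomes."""
    chroms = rng.choice(list(layout.chroms), size=100)
    starts = np.array([rng.integers(0, layout[c] - 5_000) for c in chroms])
    lengths = rng.integers(1, 5_000, size=100)
    return make_intervals(chroms, starts, starts + lengths)


@pytest.fixture
def fast_sim_config():
    """Small simulation for tests that only need structure, not power."""
    return SimulationConfig(
        seed=3,
        n_chroms=1,
        chrom_length=800_000,
        n_genes=60,
        n_tf_peaks=20,
        n_broad_domains=3,
        domain_width_range=(5_000, 15_000),
    )


def brute_force_overlap_counts(queries: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """O(n*m) oracle for >= 1 bp interval overlap counting."""
    out = np.zeros(len(queries), dtype=int)
    subs = list(subjects.itertuples(index=False))
    for i, q in enumerate(queries.itertuples(index=False)):
        out[i] = sum(
            1 for s in subs if s.chrom == q.chrom and s.start < q.end and s.end > q.start
        )
    return out
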