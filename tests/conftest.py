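import numpy as np
import pytest

from vertitrace import synthetic_data as sim
from vertitrace.seqio import read_newick


@pytest.fixture
def small_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — a balanced 4-tip rooted tree."""
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def island_genome():
    """50 kb high-GC genome with one 10 kb low-GC island at [20000, 30000)."""
    return sim.sim_genome_with_islands(
        50_000,
        islands=[(20_000, 30_000, (0.30, 0.20, 0.20, 0.30))],
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
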