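import numpy as np
import pytest

from rcwgbs import (
    GenomeSequence,
    Methylome,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """60 kb synthetic genome with truth and deep (40x) observed methylome."""
    cfg = SimulationConfig(genome_length=60_000, n_islands=4, mean_depth=40.0, seed=5)
    genome, truth, methylome = simulate_dataset(cfg)
    return genome, truth, methylome


@pytest.fixture
def toy_genome():
    # chrT: CpGs at positions 3, 9, 15, 21 (C of each CG)
    seq = "ATCGATTTCGATTTCGATTTCGATTT"
    return GenomeSequence({"chrT": seq})


@pytest.fixture
def toy_methylome():
    pos = np.array([3, 9, 15, 21])
    meth = np.array([4, 0, 2, 3])
    unmeth = np.array([0, 4, 2, 0])
    return Methylome({"chrT": (pos, meth, unmeth)})
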