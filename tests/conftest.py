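import numpy as np
import pytest

from ironmats.io_formats import AlignmentInterval, GeneModel
from ironmats.synthetic_data import SimulationConfig, simulate_catalog


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated catalog shared across tests."""
    return simulate_catalog(SimulationConfig(seed=7, n_zotus=3, genomes_per_zotu=4,
                                             n_background_genes=8))


def random_genes(rng, n_genes, contig_id="c1", contig_length=100_000):
    """Non-overlapping random genes on one contig."""
    genes = []
    pos = 0
    for i in range(n_genes):
        gap = int(rng.integers(0, 200))
        length = int(rng.integers(100, 2000))
        start = pos + gap
        end = start + length
        if end > contig_length:
            break
        genes.append(GeneModel(f"g{i}", contig_id, start, end))
        pos = end
    return genes


def random_intervals(rng, n, contig_id="c1", contig_length=100_000, max_len=300):
    out = []
    for i in range(n):
        start = int(rng.integers(0, contig_length - max_len))
        length = int(rng.integers(1, max_len))
        out.append(AlignmentInterval(contig_id, start, start + length, f"r{i}"))
    return out
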