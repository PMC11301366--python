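import numpy as np
import pytest

from enhscope import SimulationConfig, simulate
from enhscope.core import GenomicInterval
from enhscope.clustering import TagCluster


SMALL_SIM = SimulationConfig(
    seed=3,
    n_samples=8,
    n_genes=40,
    n_enhancers=30,
    n_noise_sites=100,
    n_chromosomes=2,
    genome_length=8_000_000,
    library_size_range=(400_000, 800_000),
    n_snps=20,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic cohort shared across tests."""
    return simulate(SMALL_SIM)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def make_tc(chrom, start, end, strand, counts, tc_id="TC", tpm=None, summit=None):
    tc = TagCluster(
        id=tc_id,
        interval=GenomicInterval(chrom, start, end, strand),
        summit=start if summit is None else summit,
        counts=np.asarray(counts, dtype=np.int64),
    )
    tc.tpm = None if tpm is None else np.asarray(tpm, dtype=float)
    return tc


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(
            GenomicInterval(
                str(rng.choice(chroms)),
                start,
                start + int(rng.integers(1, max_len)),
            )
        )
    return out
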