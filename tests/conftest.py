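import numpy as np
import pytest

from glioprog.genome import ReferenceGenome, reverse_complement
from glioprog.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three matched pairs on a 2 x 400 kb genome, default noise."""
    return simulate_cohort(SimulationConfig(seed=11, n_patients=3))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Two matched pairs emitted at noise 0 (rounded expectations)."""
    return simulate_cohort(SimulationConfig(seed=12, n_patients=2, noise=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(202)


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(5)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return ReferenceGenome(
        {
            "chr1": bytearray(bases[rng.integers(0, 4, 50_000)].tobytes()),
            "chr2": bytearray(bases[rng.integers(0, 4, 50_000)].tobytes()),
        }
    )


def oracle_microhomology(junction, genome, max_len=20, min_len=2):
    """Exhaustive string-comparison microhomology oracle.

    Builds the retained A tail and the displaced B flank as whole strings
    (slicing plus whole-segment reverse complement) and counts their
    common suffix — an independent path from the per-base walk in the
    package.
    """
    seq_a = genome.sequence(junction.chrom_a)
    seq_b = genome.sequence(junction.chrom_b)
    if junction.orient_a == "+":
        a_tail = seq_a[: junction.pos_a + 1][-max_len:]
    else:
        a_tail = reverse_complement(seq_a[junction.pos_a :])[-max_len:]
    if junction.orient_b == "-":
        b_flank = seq_b[: junction.pos_b][-max_len:]
    else:
        b_flank = reverse_complement(seq_b[junction.pos_b + 1 :])[-max_len:]
    n = 0
    while (
        n < min(len(a_tail), len(b_flank), max_len)
        and a_tail[-1 - n] == b_flank[-1 - n]
    ):
        n += 1
    return n if n >= min_len else 0
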