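import numpy as np
import pytest

from spikedomains import fragio, synth


@pytest.fixture(scope="session")
def toy_genomes():
    """2 x 5 Mb primary chromosomes + one 500 kb spike chromosome."""
    return synth.toy_genome()


@pytest.fixture
def primary_sizes(toy_genomes):
    return toy_genomes[0]


@pytest.fixture
def spike_sizes(toy_genomes):
    return toy_genomes[1]


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_region_set(rng, label, chrom_len=10_000, n_max=8,
                      chroms=("toyA", "toyB")):
    """Small random non-overlapping region set on tiny toy chromosomes."""
    intervals = []
    for chrom in chroms:
        n = int(rng.integers(0, n_max + 1))
        if n == 0:
            continue
        cuts = np.sort(rng.choice(chrom_len, size=2 * n, replace=False))
        for i in range(n):
            s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
            if e > s:
                intervals.append((chrom, s, e))
    return fragio.regions_from_intervals(label, intervals)
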