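"""Shared fixtures: small synthetic genomes and communities.

Expensive artifacts are session-scoped; everything is generated from fixed
seeds so the suite is fully deterministic.
"""

import numpy as np
import pytest

from longbin.records import SeqRecord
from longbin.simdata import (CommunityMember, CommunitySpec, GenomeSpec,
                             ReadSimSpec, build_community, generate_genome,
                             simulate_reads)


@pytest.fixture(scope="session")
def genome_50k() -> SeqRecord:
    return generate_genome(GenomeSpec("g50", 50000, 0.5, signature_seed=11),
                           rng_seed=1)


@pytest.fixture(scope="session")
def genome_50k_other() -> SeqRecord:
    return generate_genome(GenomeSpec("h50", 50000, 0.45, signature_seed=77),
                           rng_seed=1)


@pytest.fixture(scope="session")
def two_genome_reads():
    """Two equal-length genomes at 4:1 abundance with 2,000 long reads."""
    spec = CommunitySpec(
        [CommunityMember(GenomeSpec("A", 50000, 0.45, 1), 0.8),
         CommunityMember(GenomeSpec("B", 50000, 0.55, 2), 0.2)],
        rng_seed=5)
    community = build_community(spec)
    reads, truth = simulate_reads(
        community, ReadSimSpec(mean_length=3000, length_sd=600, n_reads=2000,
                               error_rate=0.003, rng_seed=7))
    return community, reads, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def random_dna(n: int, seed: int = 0) -> str:
    r = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in r.integers(0, 4, size=n))
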