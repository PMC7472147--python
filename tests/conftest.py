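import numpy as np
import pytest

from viroseek import synthetic_data as sd
from viroseek.records import Read


@pytest.fixture(scope="session")
def small_community():
    """A small but complete community: host, bacterium, both viral genomes."""
    return sd.default_demo_community(
        7, n_pairs=4000, host_length=40_000, bacterial_length=20_000
    )


@pytest.fixture(scope="session")
def parvo_genome():
    return sd.make_genome(sd.parvovirus_like_spec(), 17)


@pytest.fixture(scope="session")
def polyo_genome():
    return sd.make_genome(sd.polyomavirus_like_spec(), 19)


def make_read(rid, bases, qual=30, mate=None):
    return Read(rid, bases, np.full(len(bases), qual, dtype=np.uint8), mate=mate)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def random_protein(rng, n):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, n))
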