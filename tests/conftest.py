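import numpy as np
import pytest

from crisprbench import SimConfig, make_locus_fixture, simulate_reads


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240529)


@pytest.fixture(scope="session")
def matched_site_seq():
    """60-nt sequence with exactly one TTTA + 21-nt spacer + AGGAAT site."""
    spacer = "GACTGACTGACTGACTGACTG"
    return "C" * 15 + "TTTA" + spacer + "AGGAAT" + "C" * 14


@pytest.fixture(scope="session")
def small_fixture():
    """A simulated locus with a modest read set shared across tests."""
    config = SimConfig(seed=11, n_reads=400)
    locus = make_locus_fixture(config)
    reads, truth = simulate_reads(locus, config)
    return config, locus, reads, truth
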