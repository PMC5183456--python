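import numpy as np
import pytest

from phagelgt.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """10 genomes, 25 planted events, light post-transfer noise."""
    config = SimConfig(
        n_genomes=10, n_cds_per_genome=40, n_events=25,
        cds_length_codons=60, n_subs_per_event=2.0, seed=7,
    )
    return simulate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def random_cds(rng, n_codons):
    """ATG + random non-stop codons + TAA."""
    stops = {"TAA", "TAG", "TGA"}
    body = []
    while len(body) < n_codons - 2:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in stops:
            body.append(codon)
    return "ATG" + "".join(body) + "TAA"
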