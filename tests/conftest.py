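import numpy as np
import pytest

from virodiv.popgen import Genome, Population, generate_reference


@pytest.fixture(scope="session")
def focal_genome() -> Genome:
    """15-kb focal reference used across scenario tests."""
    return generate_reference(15000, gc=0.40, seed=7)


@pytest.fixture(scope="session")
def single_population(focal_genome) -> Population:
    return Population(genomes=[focal_genome], abundances=[1.0])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_seq(n: int, seed: int = 0) -> str:
    r = np.random.default_rng(seed)
    return "".join(r.choice(list("ACGT"), size=n))


def mutate_at(seq: str, positions, offset_map=None) -> str:
    """Deterministic single-base substitutions (A->C->G->T->A) at 0-based positions."""
    cyc = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = cyc[out[p]]
    return "".join(out)
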