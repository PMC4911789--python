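import numpy as np
import pytest

from anikit.genome_io import Genome
from anikit.synthetic import random_genome


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point-substitute each base with probability rate (never to itself)."""
    arr = list(seq)
    for i, c in enumerate(arr):
        if rng.random() < rate:
            arr[i] = "ACGT"[("ACGT".index(c) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


@pytest.fixture(scope="session")
def small_genome_with_genes():
    """A 30-kb synthetic genome with 20 planted genes (shared across tests)."""
    return random_genome(30_000, 20, (300, 600), seed=101, genome_id="g30k")


@pytest.fixture
def tiny_genome() -> Genome:
    return Genome("tiny", (("c1", "ACGTACGTAACCGGTTACGT"),))
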