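import numpy as np
import pytest

from ribofilt.reference_library import ReferenceSequence, partition_by_node

BASES = np.array(list("ACGT"))


def random_dna(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20230123)


@pytest.fixture
def small_partition():
    """A tiny two-partition library: one insect, one vertebrate reference."""
    rng = np.random.default_rng(7)
    ins = ReferenceSequence(
        "ins1", random_dna(rng, 400),
        ("Eukaryota", "Arthropoda", "Insecta", "Aedes aegypti"),
    )
    non = ReferenceSequence(
        "non1", random_dna(rng, 400),
        ("Eukaryota", "Chordata", "Vertebrata", "Homo sapiens"),
    )
    return partition_by_node([ins, non], "Insecta")
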