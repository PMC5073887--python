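import numpy as np
import pytest

from indelbias import IndelLocus, ReferenceGenome, ScoringScheme

#: the paper-style non-repetitive flanks of the worked insertion example
FLANK_U = "GATTACAGATTACAGATTACAGATT"
FLANK_V = "GGCCTTGGCCTTGGCCTTGGCCTTG"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


@pytest.fixture
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture
def repeat_genome():
    """Genome embedding the T(CA)3G repeat context; the anchored deletion
    TCA|T at the repeat start has five equivalent gap placements."""
    rng = np.random.default_rng(42)
    left, right = random_dna(rng, 60), random_dna(rng, 60)
    genome = ReferenceGenome({"chr1": left + "TCACACAG" + right})
    locus = IndelLocus("chr1", len(left) + 1, "TCA", ("T",))
    return genome, locus


@pytest.fixture
def insertion_genome():
    """Genome embedding the uAv context of the worked insertion example; the
    alt allele ACGA admits exactly two optimal affine alignments."""
    rng = np.random.default_rng(7)
    left, right = random_dna(rng, 40), random_dna(rng, 40)
    genome = ReferenceGenome({"chrI": left + FLANK_U + "A" + FLANK_V + right})
    locus = IndelLocus("chrI", len(left) + len(FLANK_U) + 1, "A", ("ACGA",))
    return genome, locus


@pytest.fixture
def plain_genome():
    """Genome with an unambiguous 3-bp deletion GTAC|G in repeat-free context."""
    rng = np.random.default_rng(11)
    left, right = random_dna(rng, 60), random_dna(rng, 60)
    genome = ReferenceGenome({"c": left + "TTGTACGG" + right})
    locus = IndelLocus("c", len(left) + 3, "GTAC", ("G",))
    return genome, locus
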