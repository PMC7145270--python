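import numpy as np
import pytest
from hypothesis import settings

from pamprofiler import AmpliconTarget, ReporterDesign

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def design() -> ReporterDesign:
    return ReporterDesign()


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def plus_target() -> AmpliconTarget:
    """A 180-bp amplicon with a forward-strand protospacer whose positions
    4 and 5 are C (so CBE conversion tests have editable cytosines)."""
    rng = np.random.default_rng(17)
    left = random_dna(rng, 60)
    protospacer = "GAT" + "CC" + random_dna(rng, 16)  # C at positions 4 and 5
    pam_seq = "CTGG"
    right = random_dna(rng, 80)
    amplicon = left + protospacer + pam_seq + right
    return AmpliconTarget.locate("E1", amplicon, protospacer, "NNGG", "+")


@pytest.fixture(scope="session")
def minus_target(plus_target) -> AmpliconTarget:
    """The same locus encoded on the reverse strand of the amplicon."""
    from pamprofiler._seq import revcomp

    amplicon = revcomp(plus_target.sequence)
    return AmpliconTarget.locate("E1rc", amplicon, plus_target.protospacer, "NNGG", "-")
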