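import numpy as np
import pytest
from hypothesis import settings

from tssgrammar import seqmodel, synth

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_library():
    return synth.demo_motifs()


@pytest.fixture(scope="session")
def nrf1(demo_library):
    return demo_library[0]


@pytest.fixture()
def toy_genome():
    """Two small contigs with deterministic content."""
    rng = np.random.default_rng(123)
    return {
        "chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)]),
        "chr2": "ACGTACGTACGTACGT",
    }


@pytest.fixture()
def small_windows():
    """Ten 31-bp plus-strand windows (up=20, down=10) with fixed content."""
    rng = np.random.default_rng(7)
    mat = rng.integers(0, 4, size=(10, 31)).astype(np.uint8)
    return synth.as_windows(mat, up=20, down=10)


def consensus_window(pwm, center, up=150, down=100, fill="A"):
    """A single window with the motif consensus written at a given center."""
    L = up + down + 1
    seq = list(fill * L)
    start = center + up - pwm.center_index
    cons = [seqmodel.IUPAC[c][0] for c in pwm.consensus]
    seq[start : start + len(pwm)] = cons
    return seqmodel.AnchoredWindow("w0", "chr", up, "+", up, down,
                                   "".join(seq))
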