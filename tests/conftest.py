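import numpy as np
import pytest

from profscan.profile import ProfileHMM, configure_local


def random_search_profile(rng: np.random.Generator, M: int, concentration: float = 1.0):
    """A random valid local search profile (uniform null)."""
    me = rng.dirichlet(np.ones(4) * concentration, size=M)
    tr = np.zeros((M, 7))
    tr[:, 0:3] = rng.dirichlet(np.ones(3), size=M)
    tr[:, 3:5] = rng.dirichlet(np.ones(2), size=M)
    tr[:, 5:7] = rng.dirichlet(np.ones(2), size=M)
    hmm = ProfileHMM(
        name="rand", match_emit=me, insert_emit=np.tile([0.25] * 4, (M, 1)),
        transitions=tr, null1=np.full(4, 0.25), consensus="A" * M,
    )
    return configure_local(hmm)


def random_dna(rng: np.random.Generator, L: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=L)) if L else ""


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
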