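import numpy as np
import pytest

from pathhmm import Network, SimilarityTable


@pytest.fixture
def chain3() -> Network:
    """Unit-weight chain a-b-c."""
    return Network("chain", edges=[("a", "b", 1.0), ("b", "c", 1.0)])


@pytest.fixture
def triangle() -> Network:
    """Triangle with weights ab=1, ac=2/... scaled into (0,1]: ab=0.1, ac=0.2, bc=0.3."""
    return Network(
        "tri", edges=[("a", "b", 0.1), ("a", "c", 0.2), ("b", "c", 0.3)]
    )


@pytest.fixture
def star() -> Network:
    """Node a with neighbors b (w=0.25) and c (w=0.75): weight ratio 1:3."""
    return Network("star", edges=[("a", "b", 0.25), ("a", "c", 0.75)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


def make_sim(entries) -> SimilarityTable:
    t = SimilarityTable()
    for u, v, score in entries:
        t.set(u, v, score)
    return t
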