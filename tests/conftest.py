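import numpy as np
import pytest

from mscomplexity import Alphabet, SymbolicSequence


@pytest.fixture
def abcd() -> Alphabet:
    return Alphabet(("A", "B", "C", "D"))


@pytest.fixture
def make_seq(abcd):
    """Build a SymbolicSequence from a label string like 'ACCCAADBBA'."""

    def _make(text: str, alphabet: Alphabet = abcd) -> SymbolicSequence:
        return SymbolicSequence.from_labels(text, alphabet)

    return _make


@pytest.fixture
def make_iid(abcd):
    """iid uniform sequence over a given alphabet size."""

    def _make(n: int, A: int = 4, seed: int = 0) -> SymbolicSequence:
        rng = np.random.default_rng(seed)
        return SymbolicSequence(rng.integers(0, A, n), Alphabet.default(A))

    return _make
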