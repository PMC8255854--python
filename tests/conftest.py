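import pytest

from shortmsa import (
    Alignment,
    Alphabet,
    SequenceSet,
    example_two_letter_metric,
    unit_metric,
)


@pytest.fixture
def cg_alphabet():
    return Alphabet(("C", "G"))


@pytest.fixture
def unit_cg(cg_alphabet):
    return unit_metric(cg_alphabet)


@pytest.fixture
def two_letter_metric():
    """d(C,G)=2 with unit gap costs: metric but not gap-dominant."""
    return example_two_letter_metric()


@pytest.fixture
def set_ccg():
    """Three length-3 sequences whose trivial alignment is beatable under the unit metric."""
    return SequenceSet.from_strings(["CCG", "GCG", "CGC"])


@pytest.fixture
def set_cg():
    """Three length-2 sequences whose trivial alignment is beatable under the two-letter metric."""
    return SequenceSet.from_strings(["CG", "GC", "GG"])


@pytest.fixture
def example_i_alignment(set_ccg):
    return Alignment(rows=("CCG-", "GCG-", "-CGC"), source=set_ccg)


@pytest.fixture
def example_ii_alignment(set_cg):
    return Alignment(rows=("-CG", "GC-", "G-G"), source=set_cg)
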