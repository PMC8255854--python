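"""Alignment model, pairwise and sum-of-pairs costs, trivial alignment, normalization."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shortmsa import (
    Alignment,
    Alphabet,
    SequenceSet,
    ShortMSAError,
    normalize,
    pairwise_cost,
    random_metric,
    sp_cost,
    trivial_alignment,
    unit_metric,
)


class TestDataModel:
    def test_alphabet_rejects_gap_and_duplicates(self):
        with pytest.raises(ShortMSAError):
            Alphabet(("A", "-"))
        with pytest.raises(ShortMSAError):
            Alphabet(("A", "—"))  # typographic dash is a gap alias
        with pytest.raises(ShortMSAError):
            Alphabet(("A", "A"))
        with pytest.raises(ShortMSAError):
            Alphabet(())

    def test_sequence_set_uppercases_and_checks_alphabet(self):
        s = SequenceSet.from_strings(["ccg", "gcg"])
        assert s.sequences == ("CCG", "GCG")
        assert set(s.alphabet) == {"C", "G"}
        with pytest.raises(ShortMSAError):
            SequenceSet.from_strings(["CT"], alphabet=Alphabet(("C", "G")))

    def test_duplicate_ids_rejected_duplicate_content_allowed(self):
        SequenceSet.from_strings(["CG", "CG"])  # multiset ok
        with pytest.raises(ShortMSAError):
            SequenceSet.from_strings(["CG", "GC"], ids=["a", "a"])

    def test_alignment_rows_must_degap_to_sources(self):
        src = SequenceSet.from_strings(["CG", "GC"])
        Alignment(rows=("CG-", "-GC"), source=src)
        with pytest.raises(ShortMSAError):
            Alignment(rows=("GC-", "-CG"), source=src)  # swapped rows
        with pytest.raises(ShortMSAError):
            Alignment(rows=("CG-", "GC"), source=src)  # ragged


class TestPairwiseCost:
    def test_single_mismatch_under_unit_metric(self, unit_cg):
        assert pairwise_cost("CCG", "GCG", unit_cg) == 1

    def test_identical_rows_cost_zero(self, unit_cg, two_letter_metric):
        for scheme in (unit_cg, two_letter_metric):
            assert pairwise_cost("GCG", "GCG", scheme) == 0

    def test_two_letter_metric_double_mismatch(self, two_letter_metric):
        assert pairwise_cost("CG", "GC", two_letter_metric) == 4

    def test_length_mismatch_and_foreign_symbol_error(self, unit_cg):
        with pytest.raises(ShortMSAError):
            pairwise_cost("CG", "C", unit_cg)
        with pytest.raises(ShortMSAError):
            pairwise_cost("CT", "CG", unit_cg)

    def test_symmetric_in_arguments(self, two_letter_metric):
        assert pairwise_cost("C-G", "GC-", two_letter_metric) == pairwise_cost(
            "GC-", "C-G", two_letter_metric
        )


class TestSumOfPairs:
    def test_worked_three_letter_instance(self, example_i_alignment, unit_cg):
        report = sp_cost(example_i_alignment, unit_cg)
        assert report.total == 5
        assert report.per_column == (3, 0, 0, 2)

    def test_worked_two_letter_instance(self, example_ii_alignment, two_letter_metric):
        report = sp_cost(example_ii_alignment, two_letter_metric)
        assert report.total == 6
        assert report.per_column == (2, 2, 2)

    def test_identical_sequences_cost_zero(self, unit_cg):
        s = SequenceSet.from_strings(["CG", "CG", "CG"])
        assert sp_cost(trivial_alignment(s), unit_cg).total == 0

    def test_column_and_pair_decompositions_agree(self, example_i_alignment, unit_cg):
        r = sp_cost(example_i_alignment, unit_cg)
        assert r.total == sum(r.per_column) == sum(r.per_pair.values())
        assert len(r.per_pair) == 3  # k(k-1)/2 for k=3


class TestTrivialAlignment:
    def test_gapless_rows_and_worked_costs(self, set_ccg, set_cg, unit_cg, two_letter_metric):
        t1 = trivial_alignment(set_ccg)
        assert t1.rows == ("CCG", "GCG", "CGC") and t1.length == 3
        assert sp_cost(t1, unit_cg).total == 6
        t2 = trivial_alignment(set_cg)
        assert sp_cost(t2, two_letter_metric).total == 8

    def test_single_sequence_costs_nothing(self, unit_cg):
        s = SequenceSet.from_strings(["CGC"])
        assert sp_cost(trivial_alignment(s), unit_cg).total == 0

    def test_unequal_lengths_error_rather_than_pad(self):
        s = SequenceSet.from_strings(["CG", "C"])
        with pytest.raises(ShortMSAError):
            trivial_alignment(s)


class TestNormalize:
    def test_drops_all_gap_columns_only(self):
        src = SequenceSet.from_strings(["C", "G"])
        aln = Alignment(rows=("C--", "G--"), source=src)
        assert normalize(aln).rows == ("C", "G")

    def test_idempotent_on_canonical(self, example_i_alignment):
        assert normalize(example_i_alignment) is example_i_alignment

    def test_preserves_degap_invariant_and_cost(self, unit_cg):
        src = SequenceSet.from_strings(["CG", "GC"])
        aln = Alignment(rows=("C-G-", "G-C-"), source=src)
        norm = normalize(aln)
        assert norm.rows == ("CG", "GC")
        assert sp_cost(norm, unit_cg).total == sp_cost(aln, unit_cg).total


# --- property tests -------------------------------------------------------

_ALPHA = Alphabet(("A", "C", "G"))


@st.composite
def random_alignments(draw):
    k = draw(st.integers(2, 4))
    seqs = [
        "".join(draw(st.sampled_from("ACG")) for _ in range(draw(st.integers(1, 3))))
        for _ in range(k)
    ]
    src = SequenceSet.from_strings(seqs, alphabet=_ALPHA)
    width = max(len(s) for s in seqs) + draw(st.integers(0, 2))
    rows = []
    for s in seqs:
        gap_at = sorted(draw(st.permutations(range(width)))[: width - len(s)])
        row, it = [], iter(s)
        for i in range(width):
            row.append("-" if i in gap_at else next(it))
        rows.append("".join(row))
    return Alignment(rows=tuple(rows), source=src)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(aln=random_alignments(), seed=st.integers(0, 100))
def test_sp_cost_properties(aln, seed):
    """Row-permutation invariance, decomposition agreement, scaling,
    and normalization invariance of the SP cost under random metrics."""
    scheme = random_metric(_ALPHA, seed)
    r = sp_cost(aln, scheme)
    assert r.total == sum(r.per_column) == sum(r.per_pair.values())
    # row permutation leaves the double sum unchanged
    perm = list(range(aln.k))[::-1]
    permuted = Alignment(
        rows=tuple(aln.rows[i] for i in perm),
        source=SequenceSet(
            tuple(aln.source.records[i] for i in perm), aln.source.alphabet
        ),
    )
    assert sp_cost(permuted, scheme).total == r.total
    # linear scaling of the scheme scales the cost
    assert sp_cost(aln, scheme.scale(3)).total == 3 * r.total
    # all-gap columns contribute nothing
    assert sp_cost(normalize(aln), scheme).total == r.total


@settings(max_examples=40, derandomize=True, deadline=None)
@given(aln=random_alignments())
def test_unit_cost_counts_mismatched_pairs(aln):
    """Under the unit metric the SP total equals a direct mismatch count."""
    unit = unit_metric(_ALPHA)
    expected = sum(
        (a != b)
        for r1, r2 in itertools.combinations(aln.rows, 2)
        for a, b in zip(r1, r2)
        if not (a == "-" and b == "-")
    )
    assert sp_cost(aln, unit).total == expected
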