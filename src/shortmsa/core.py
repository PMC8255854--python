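"""Alignment data model and sum-of-pairs scoring.

A multiple alignment of sequences ``s_1 .. s_k`` is a ``k x l`` character
matrix over the alphabet plus a reserved gap symbol: each row, with its gaps
removed, reproduces its source sequence exactly.  The sum-of-pairs (SP) cost
of the alignment under a score scheme ``d`` is

    SP(A) = sum_{i<j} sum_c d(A[i][c], A[j][c])

i.e. the total pairwise alignment cost over all k*(k-1)/2 row pairs, which
decomposes equivalently over columns.  Because ``d(-, -) = 0`` for every
valid scheme, columns consisting only of gaps contribute nothing; a
*canonical* alignment contains no such column.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

GAP = "-"
# typographic dashes (en/em dash, minus sign) are accepted on input
GAP_ALIASES = frozenset({"-", "–", "—", "−"})


class ShortMSAError(ValueError):
    """Base class for domain errors raised by this package."""


def normalize_gaps(text: str) -> str:
    """Map every accepted gap glyph to the canonical ASCII ``-``."""
    return "".join(GAP if ch in GAP_ALIASES else ch for ch in text)


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of single characters; the gap symbol is never a member."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ShortMSAError("alphabet must be non-empty")
        seen = set()
        for s in self.symbols:
            if len(s) != 1:
                raise ShortMSAError(f"alphabet symbols are single characters, got {s!r}")
            if s in GAP_ALIASES:
                raise ShortMSAError("the gap character is reserved and cannot be an alphabet symbol")
            if s in seen:
                raise ShortMSAError(f"duplicate alphabet symbol {s!r}")
            seen.add(s)

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "Alphabet":
        """Infer an alphabet from sequence content (sorted for determinism)."""
        chars = sorted({ch for s in seqs for ch in s})
        return cls(tuple(chars))

    def __contains__(self, ch: object) -> bool:
        return ch in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


@dataclass(frozen=True)
class SequenceSet:
    """Ordered multiset of sequences over one alphabet.

    Record ids are unique; duplicate sequence *content* is allowed (in any
    optimal alignment identical sequences end up aligned identically and
    contribute zero cost to each other, so multiset inputs are harmless).
    """

    records: tuple[tuple[str, str], ...]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.records:
            raise ShortMSAError("sequence set must contain at least one record")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ShortMSAError("record ids must be unique")
        for rid, seq in self.records:
            for ch in seq:
                if ch in GAP_ALIASES:
                    raise ShortMSAError(f"record {rid!r} contains the reserved gap character")
                if ch not in self.alphabet:
                    raise ShortMSAError(f"record {rid!r} contains {ch!r}, not in alphabet")

    @classmethod
    def from_strings(
        cls,
        seqs: Sequence[str],
        ids: Sequence[str] | None = None,
        alphabet: Alphabet | None = None,
    ) -> "SequenceSet":
        seqs = [s.upper() for s in seqs]
        if ids is None:
            ids = [f"s{i + 1}" for i in range(len(seqs))]
        if alphabet is None:
            alphabet = Alphabet.from_sequences(seqs)
        return cls(tuple(zip(ids, seqs)), alphabet)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    @property
    def k(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Alignment:
    """``k x l`` matrix of alphabet-or-gap characters tied to its source set.

    Invariant: row ``i`` with gaps removed equals source sequence ``i``.
    All-gap columns are tolerated (they cost nothing) but non-canonical;
    :func:`normalize` removes them.
    """

    rows: tuple[str, ...]
    source: SequenceSet

    def __post_init__(self) -> None:
        if len(self.rows) != self.source.k:
            raise ShortMSAError("alignment must have one row per source sequence")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ShortMSAError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        for row, (rid, seq) in zip(self.rows, self.source.records):
            if row.replace(GAP, "") != seq:
                raise ShortMSAError(
                    f"row for {rid!r} does not de-gap to its source sequence "
                    f"({row!r} vs {seq!r})"
                )

    @property
    def length(self) -> int:
        """Number of columns (1-based in human-readable reports)."""
        return len(self.rows[0])

    @property
    def k(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> tuple[str, ...]:
        return tuple(row[i] for row in self.rows)

    def columns(self) -> Iterable[tuple[str, ...]]:
        for i in range(self.length):
            yield self.column(i)

    def is_canonical(self) -> bool:
        return all(any(ch != GAP for ch in col) for col in self.columns())


@dataclass(frozen=True)
class CostReport:
    """SP cost with its column and row-pair decompositions.

    Both decompositions are views of the same double sum, so
    ``total == sum(per_column) == sum(per_pair.values())`` always holds.
    """

    total: int | float
    per_column: tuple[int | float, ...]
    per_pair: dict[tuple[int, int], int | float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert _close(self.total, sum(self.per_column))
        if self.per_pair:
            assert _close(self.total, sum(self.per_pair.values()))


def _close(a, b, tol: float = 1e-9) -> bool:
    if isinstance(a, int) and isinstance(b, int):
        return a == b
    return abs(a - b) <= tol


def pairwise_cost(row1: str, row2: str, scheme) -> int | float:
    """Cost of a pairwise alignment: the positionwise sum of scheme distances.

    Rows must have equal length; characters must lie in the scheme's domain.
    """
    if len(row1) != len(row2):
        raise ShortMSAError(f"aligned rows differ in length ({len(row1)} vs {len(row2)})")
    return sum(scheme.d(a, b) for a, b in zip(row1, row2))


def sp_cost(aln: Alignment, scheme) -> CostReport:
    """Sum-of-pairs cost of a multiple alignment under a score scheme."""
    per_column = tuple(
        sum(scheme.d(col[i], col[j]) for i, j in itertools.combinations(range(len(col)), 2))
        for col in aln.columns()
    )
    per_pair = {
        (i, j): pairwise_cost(aln.rows[i], aln.rows[j], scheme)
        for i, j in itertools.combinations(range(aln.k), 2)
    }
    total = sum(per_pair.values()) if per_pair else 0
    return CostReport(total=total, per_column=per_column, per_pair=per_pair)


def trivial_alignment(seqs: SequenceSet) -> Alignment:
    """Write the sequences under one another without inserting any gaps.

    Defined only for equal-length inputs; unequal lengths raise rather than
    silently padding, because padded "trivial" alignments would corrupt the
    optimality checks that compare against this construction.
    """
    lengths = {len(s) for s in seqs.sequences}
    if len(lengths) != 1:
        raise ShortMSAError(
            f"trivial alignment requires equal-length sequences, got lengths {sorted(lengths)}"
        )
    return Alignment(rows=seqs.sequences, source=seqs)


def normalize(aln: Alignment) -> Alignment:
    """Drop all-gap columns; SP cost is unchanged under any valid scheme."""
    keep = [i for i, col in enumerate(aln.columns()) if any(ch != GAP for ch in col)]
    if len(keep) == aln.length:
        return aln
    rows = tuple("".join(row[i] for i in keep) for row in aln.rows)
    return Alignment(rows=rows, source=aln.source)
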