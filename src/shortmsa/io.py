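"""Reading and writing sequences and alignments.

Unaligned input is FASTA or plain one-sequence-per-line text; aligned input
and output are aligned FASTA (equal-length rows, gaps as ``-``).  Sequences
are uppercased on read and typographic dashes are normalized to the ASCII
gap, so the worked instances can be pasted verbatim.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    GAP,
    Alignment,
    Alphabet,
    SequenceSet,
    ShortMSAError,
    normalize_gaps,
)


def _read_records(path: str | Path) -> list[tuple[str, str]]:
    # normalize typographic dashes up front: Bio.Seq is ASCII-only
    text = normalize_gaps(Path(path).read_text())
    if not text.strip():
        raise ShortMSAError(f"{path}: empty input")
    if text.lstrip().startswith(">"):
        records = [
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(_io.StringIO(text), "fasta")
        ]
    else:
        records = [
            (f"s{i + 1}", line.strip())
            for i, line in enumerate(text.splitlines())
            if line.strip()
        ]
    return [(rid, normalize_gaps(seq).upper()) for rid, seq in records]


def read_sequences(path: str | Path, alphabet: Alphabet | None = None) -> SequenceSet:
    """Read unaligned sequences (FASTA or plain text) into a SequenceSet.

    The alphabet is inferred from content unless declared; a gap character
    inside an input sequence is an error (the gap is reserved for
    alignments).
    """
    records = _read_records(path)
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise ShortMSAError(f"{path}: duplicate record ids")
    for rid, seq in records:
        if GAP in seq:
            raise ShortMSAError(f"{path}: record {rid!r} contains the reserved gap character")
    if alphabet is None:
        alphabet = Alphabet.from_sequences(seq for _, seq in records)
    return SequenceSet(tuple(records), alphabet)


def read_aligned(path: str | Path, alphabet: Alphabet | None = None) -> Alignment:
    """Read an aligned FASTA file; rows keep their gaps as given.

    Normalization (dropping all-gap columns) is *not* applied: a user
    scoring a printed alignment wants the cost of that alignment as-is.
    The source SequenceSet is recovered by de-gapping the rows.
    """
    records = _read_records(path)
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise ShortMSAError(f"{path}: aligned rows have unequal lengths {sorted(lengths)}")
    degapped = [(rid, seq.replace(GAP, "")) for rid, seq in records]
    if alphabet is None:
        alphabet = Alphabet.from_sequences(seq for _, seq in degapped)
    source = SequenceSet(tuple(degapped), alphabet)
    return Alignment(rows=tuple(seq for _, seq in records), source=source)


def format_aligned_fasta(aln: Alignment) -> str:
    out = _io.StringIO()
    records = [
        SeqRecord(Seq(row), id=rid, description="")
        for row, rid in zip(aln.rows, aln.source.ids)
    ]
    SeqIO.write(records, out, "fasta")
    return out.getvalue()


def write_aligned(aln: Alignment, path: str | Path) -> None:
    Path(path).write_text(format_aligned_fasta(aln))
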