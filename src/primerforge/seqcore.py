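"""Sequence representation, validation and FASTA I/O.

Every other module works on plain uppercase DNA strings over the alphabet
``{A, C, G, T, N}`` or on :class:`Sequence` records.  Other IUPAC ambiguity
codes are rejected at construction time so that downstream match semantics
(a base either pairs or it does not) stay unambiguous.

All internal coordinates are 0-based, half-open.  The report layer converts
to 1-based inclusive for human consumption.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for invalid DNA input or malformed FASTA."""


def validate_bases(bases: str) -> str:
    """Upper-case *bases* and verify every character is in {A,C,G,T,N}.

    Raises :class:`SequenceError` naming the first offending position.
    """
    up = bases.upper()
    for i, ch in enumerate(up):
        if ch not in VALID_BASES:
            raise SequenceError(
                f"invalid base {ch!r} at position {i} (alphabet is A,C,G,T,N)"
            )
    return up


@dataclass(frozen=True)
class Sequence:
    """A validated DNA sequence with an identifier."""

    id: str
    bases: str = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.bases) == 0:
            raise SequenceError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "bases", validate_bases(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> str:
        return self.bases[start:end]


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    s = validate_bases(s)
    return s.translate(_COMPLEMENT)[::-1]


def gc_content(s: str) -> float:
    """Fraction of G+C over the full length (Ns count in the denominator only)."""
    s = validate_bases(s)
    if not s:
        raise SequenceError("gc_content of empty sequence is undefined")
    return (s.count("G") + s.count("C")) / len(s)


def read_fasta(path: Union[str, Path]) -> list[Sequence]:
    """Read a (multi-record) FASTA file into a list of :class:`Sequence`.

    The id is the header text up to the first whitespace.  Lower-case input
    is normalised; blank lines are tolerated.  Empty files, records with no
    sequence, and non-FASTA leading content raise :class:`SequenceError`
    with a line number where applicable.
    """
    path = Path(path)
    text = path.read_text()
    # Strict preamble check Bio.SeqIO does not report a line number for.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise SequenceError(
                f"{path}: line {lineno}: expected FASTA header '>' "
                f"before sequence data"
            )
        break
    else:
        raise SequenceError(f"{path}: empty FASTA file")

    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise SequenceError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(Sequence(id=rec.id, bases=str(rec.seq)))
    return out


def write_fasta(path: Union[str, Path], seqs: Iterable[Sequence], width: int = 60) -> None:
    """Write sequences as wrapped FASTA."""
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
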