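"""Sequence storage and the unified coordinate space Q.

All input sequences are concatenated into a single string S; the coordinate
universe for alignment matches is Q = S ∨ S̄, i.e. the forward concatenation
followed by an *implicit* reverse-complement half.  Positions in [0, |S|)
address the forward strand; positions in [|S|, 2|S|) address the reverse
strand.  Within the reverse half each sequence occupies the mirror of its
forward range, so mirroring never crosses sequence boundaries.  The reverse
strand is never materialized: its characters are computed on demand by
complementing the mirrored forward character.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import gzip
import io
from bisect import bisect_right
from dataclasses import dataclass
from typing import IO, Iterable, Union

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "SequenceIndex",
    "load_sequences",
    "revcomp",
    "complement",
    "COMPLEMENT",
]

_COMPLEMENT_TABLE = str.maketrans("ACGTN", "TGCAN")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_ALLOWED = frozenset("ACGTN")


def complement(base: str) -> str:
    """Complement of a single A/C/G/T/N base."""
    return COMPLEMENT[base]


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence: name, length and start offset within S."""

    name: str
    length: int
    offset: int

    @property
    def end(self) -> int:
        return self.offset + self.length


class SequenceIndex:
    """Index over the concatenated input sequences S.

    Provides name → record lookup, global-offset → (record, local offset)
    lookup, random character access over both halves of Q and the
    per-sequence strand mirror map.
    """

    def __init__(self, names: Iterable[str], seqs: Iterable[str]):
        self.records: list[SequenceRecord] = []
        self._by_name: dict[str, SequenceRecord] = {}
        parts: list[str] = []
        offset = 0
        for name, seq in zip(names, seqs):
            if name in self._by_name:
                raise ValueError(f"duplicate sequence name: {name!r}")
            if not seq:
                raise ValueError(f"empty sequence: {name!r}")
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - _ALLOWED
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains non-A/C/G/T/N characters: "
                    f"{sorted(bad)}"
                )
            rec = SequenceRecord(name, len(seq), offset)
            self.records.append(rec)
            self._by_name[name] = rec
            parts.append(seq)
            offset += len(seq)
        if not self.records:
            raise ValueError("no sequences in input")
        self.sequence: str = "".join(parts)  # S, forward strand only
        self.total_length: int = offset  # |S|
        self._starts = [r.offset for r in self.records]

    # -- lookups ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def record(self, name: str) -> SequenceRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown sequence name: {name!r}") from None

    def seq(self, name: str) -> str:
        """The forward-strand sequence of a named record."""
        rec = self.record(name)
        return self.sequence[rec.offset : rec.end]

    def global_offset(self, name: str, local: int) -> int:
        """Map (name, local offset) to a forward-strand Q position."""
        rec = self.record(name)
        if not 0 <= local < rec.length:
            raise IndexError(f"offset {local} out of range for {name!r}")
        return rec.offset + local

    def locate(self, pos: int) -> tuple[SequenceRecord, int]:
        """Map a forward-strand Q position to (record, local offset)."""
        n = self.total_length
        if not 0 <= pos < n:
            raise IndexError(f"position {pos} outside forward range [0, {n})")
        i = bisect_right(self._starts, pos) - 1
        rec = self.records[i]
        return rec, pos - rec.offset

    # -- the two-stranded coordinate space Q -----------------------------

    def is_reverse(self, pos: int) -> bool:
        """True if pos addresses the reverse-complement half of Q."""
        n = self.total_length
        if not 0 <= pos < 2 * n:
            raise IndexError(f"position {pos} outside Q = [0, {2 * n})")
        return pos >= n

    def mirror(self, pos: int) -> int:
        """The opposite-strand twin of a Q position (an involution).

        A forward position of sequence g maps into g's mirrored range in
        the reverse half and vice versa; the mirror of local offset i in a
        sequence of length L is local offset L-1-i on the other strand.
        """
        n = self.total_length
        if pos < n:
            rec, local = self.locate(pos)
            return n + rec.offset + (rec.length - 1 - local)
        rec, local = self.locate(pos - n)
        return rec.offset + (rec.length - 1 - local)

    def char_at(self, pos: int) -> str:
        """Character of Q at pos (complemented on the reverse half)."""
        n = self.total_length
        if 0 <= pos < n:
            return self.sequence[pos]
        if n <= pos < 2 * n:
            return COMPLEMENT[self.sequence[self.mirror(pos)]]
        raise IndexError(f"position {pos} outside Q = [0, {2 * n})")

    def to_forward(self, pos: int) -> tuple[int, bool]:
        """Project a Q position to (forward position, is_reverse)."""
        if self.is_reverse(pos):
            return self.mirror(pos), True
        return pos, False


def _open_text(source: Union[str, IO]) -> IO:
    if hasattr(source, "read"):
        return source
    with open(source, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(source, "rt")
    return open(source, "rt")


def load_sequences(source: Union[str, IO]) -> SequenceIndex:
    """Read FASTA or FASTQ (plain or gzipped) into a SequenceIndex.

    The format is sniffed from the first non-blank character ('>' FASTA,
    '@' FASTQ).  FASTQ qualities are discarded; sequences are uppercased
    and U is mapped to T.  Characters outside A/C/G/T/N, duplicate names
    and empty sequences are hard errors.
    """
    handle = _open_text(source)
    text = handle.read()
    if isinstance(text, bytes):
        text = text.decode()
    stripped = text.lstrip()
    if not stripped:
        raise ValueError("no sequences in input")
    fmt = "fasta" if stripped[0] == ">" else "fastq"
    names, seqs = [], []
    for rec in SeqIO.parse(io.StringIO(text), fmt):
        names.append(rec.id)
        seqs.append(str(rec.seq))
    return SequenceIndex(names, seqs)
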