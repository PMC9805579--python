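"""PAF parsing and range-compressed matches over Q.

A pairwise alignment asserts character-level identity between runs of
positions in the unified coordinate space Q.  Rather than storing one pair
per character, each maximal run of match operations in a CIGAR becomes a
single :class:`RangeMatch` — a pair of equal-length Q ranges read in
parallel (positional convention: position ``a_start+t`` is matched to
``b_start+t``; a range in the reverse half of Q is thereby read as reverse
complement, so a forward/reverse-half pair encodes an inversion).

The sorted match array doubles as an implicit interval tree: binary search
over first-range starts plus a prefix maximum of first-range ends gives
O(log n + occ) overlap queries without explicit tree pointers.
"""

from __future__ import annotations

import gzip
import io
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, NamedTuple, Union

from .seqstore import SequenceIndex

__all__ = [
    "PafRecord",
    "RangeMatch",
    "MatchIndex",
    "parse_paf",
    "parse_cigar",
    "cigar_to_matches",
    "build_match_index",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = frozenset("MIS=X")
_TARGET_OPS = frozenset("MDN=X")
_ALLOWED_OPS = frozenset("M=XIDNS")
_MATCH_OPS = frozenset("M=")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into (length, op) pairs, validating syntax."""
    pos = 0
    ops: list[tuple[int, str]] = []
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR: {cigar!r}")
        n, op = int(m.group(1)), m.group(2)
        if n <= 0:
            raise ValueError(f"zero-length CIGAR op in {cigar!r}")
        ops.append((n, op))
        pos = m.end()
    if pos != len(cigar) or not ops:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


@dataclass(frozen=True)
class PafRecord:
    """One PAF alignment line with a base-level CIGAR (cg:Z tag)."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    residue_matches: int
    block_length: int
    mapping_quality: int
    cigar: str

    def validate(self) -> None:
        for label, length, start, end in (
            ("query", self.query_length, self.query_start, self.query_end),
            ("target", self.target_length, self.target_start, self.target_end),
        ):
            if not (0 <= start < end <= length):
                raise ValueError(
                    f"{label} interval [{start},{end}) invalid for length "
                    f"{length} ({self.query_name} vs {self.target_name})"
                )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        q = t = 0
        for n, op in parse_cigar(self.cigar):
            if op not in _ALLOWED_OPS:
                raise ValueError(f"unsupported CIGAR op {op!r} in {self.cigar!r}")
            if op in _QUERY_OPS:
                q += n
            if op in _TARGET_OPS:
                t += n
        if q != self.query_end - self.query_start:
            raise ValueError(
                f"CIGAR consumes {q} query bases but interval is "
                f"{self.query_end - self.query_start} "
                f"({self.query_name} vs {self.target_name})"
            )
        if t != self.target_end - self.target_start:
            raise ValueError(
                f"CIGAR consumes {t} target bases but interval is "
                f"{self.target_end - self.target_start} "
                f"({self.query_name} vs {self.target_name})"
            )

    def to_paf_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.query_name,
                self.query_length,
                self.query_start,
                self.query_end,
                self.strand,
                self.target_name,
                self.target_length,
                self.target_start,
                self.target_end,
                self.residue_matches,
                self.block_length,
                self.mapping_quality,
                f"cg:Z:{self.cigar}",
            )
        )


def _open_text(source: Union[str, IO]) -> IO:
    if hasattr(source, "read"):
        return source
    with open(source, "rb") as probe:
        if probe.read(2) == b"\x1f\x8b":
            return gzip.open(source, "rt")
    return open(source, "rt")


def parse_paf(
    source: Union[str, IO], index: SequenceIndex | None = None
) -> Iterator[PafRecord]:
    """Parse PAF lines into validated records.

    Each line needs the 12 mandatory columns plus a cg:Z CIGAR tag.  When a
    :class:`SequenceIndex` is given, query/target names and lengths are
    resolved against it; unknown names are hard errors.
    """
    handle = _open_text(source)
    if isinstance(handle, (bytes, str)):  # pragma: no cover - defensive
        handle = io.StringIO(handle)
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"PAF line {lineno}: fewer than 12 columns")
        cigar = None
        for tag in fields[12:]:
            if tag.startswith("cg:Z:"):
                cigar = tag[5:]
                break
        if cigar is None:
            raise ValueError(
                f"PAF line {lineno}: missing cg:Z CIGAR tag "
                "(base-level alignments are required)"
            )
        try:
            rec = PafRecord(
                query_name=fields[0],
                query_length=int(fields[1]),
                query_start=int(fields[2]),
                query_end=int(fields[3]),
                strand=fields[4],
                target_name=fields[5],
                target_length=int(fields[6]),
                target_start=int(fields[7]),
                target_end=int(fields[8]),
                residue_matches=int(fields[9]),
                block_length=int(fields[10]),
                mapping_quality=int(fields[11]),
                cigar=cigar,
            )
            rec.validate()
        except ValueError as exc:
            raise ValueError(f"PAF line {lineno}: {exc}") from None
        if index is not None:
            for name, length in (
                (rec.query_name, rec.query_length),
                (rec.target_name, rec.target_length),
            ):
                if name not in index:
                    raise ValueError(f"PAF line {lineno}: unknown sequence {name!r}")
                if index.record(name).length != length:
                    raise ValueError(
                        f"PAF line {lineno}: length {length} for {name!r} "
                        f"disagrees with FASTA ({index.record(name).length})"
                    )
        yield rec


class RangeMatch(NamedTuple):
    """A pair of equal-length Q ranges asserted character-identical.

    Position ``a_start+t`` matches ``b_start+t`` for t in [0, length); a
    range lying in the reverse half of Q is read as reverse complement by
    construction of Q.
    """

    a_start: int
    b_start: int
    length: int

    @property
    def a_end(self) -> int:
        return self.a_start + self.length

    @property
    def b_end(self) -> int:
        return self.b_start + self.length

    def flipped(self) -> "RangeMatch":
        return RangeMatch(self.b_start, self.a_start, self.length)


def cigar_to_matches(
    record: PafRecord,
    index: SequenceIndex,
    min_match_len: int = 0,
) -> list[RangeMatch]:
    """Walk a CIGAR and emit one RangeMatch per maximal exact-match run.

    The query range lives in the forward half of Q; the target range lives
    in the forward half for '+' records and in the reverse half for '−'
    records (a '−' CIGAR walks the target's reverse complement forward, so
    target consumption maps directly onto ascending reverse-half
    coordinates).  'M' runs are verified base-by-base and split at unequal
    pairs exactly like 'X'; '=' is trusted.  Runs shorter than
    ``min_match_len`` are dropped; self-identity runs (a == b) carry no
    information and are dropped too.
    """
    if min_match_len < 0:
        raise ValueError("min_match_len must be >= 0")
    n = index.total_length
    q_rec = index.record(record.query_name)
    t_rec = index.record(record.target_name)
    q_base = q_rec.offset + record.query_start
    if record.strand == "+":
        t_base = t_rec.offset + record.target_start
    else:
        # ascending coordinates along the target's reverse complement
        t_base = n + t_rec.offset + (t_rec.length - record.target_end)

    matches: list[RangeMatch] = []
    run_q = run_t = run_len = 0
    cq = ct = 0  # consumed query / target bases

    def close_run() -> None:
        nonlocal run_len
        if run_len >= max(min_match_len, 1):
            a, b = q_base + run_q, t_base + run_t
            if a != b:  # perfect self-match carries no information
                matches.append(RangeMatch(a, b, run_len))
        run_len = 0

    for op_len, op in parse_cigar(record.cigar):
        if op in _MATCH_OPS:
            if op == "M":
                # verify character identity; split runs at unequal pairs
                for t in range(op_len):
                    qp = q_base + cq + t
                    tp = t_base + ct + t
                    if index.char_at(qp) == index.char_at(tp):
                        if run_len == 0:
                            run_q, run_t = cq + t, ct + t
                        run_len += 1
                    else:
                        close_run()
            else:
                if run_len == 0:
                    run_q, run_t = cq, ct
                run_len += op_len
            cq += op_len
            ct += op_len
        else:
            close_run()
            if op in _QUERY_OPS:
                cq += op_len
            if op in _TARGET_OPS:
                ct += op_len
    close_run()
    return matches


class MatchIndex:
    """Sorted, symmetric array of RangeMatch with logarithmic overlap query.

    Every match is stored in both directions (a↔b) so that any position's
    partners are findable by querying the first range alone.  The array is
    sorted by (a_start, b_start, length); a prefix maximum over first-range
    ends lets overlap queries binary-search to the insertion point and walk
    left only while an overlap is still possible — the implicit interval
    tree over range matches.
    """

    def __init__(self, matches: Iterable[RangeMatch]):
        uniq = set()
        for m in matches:
            if m.length < 1:
                raise ValueError(f"non-positive match length: {m}")
            uniq.add(m)
            uniq.add(m.flipped())
        self.matches: list[RangeMatch] = sorted(uniq)
        self._starts = [m.a_start for m in self.matches]
        self._prefix_max_end: list[int] = []
        running = 0
        for m in self.matches:
            running = max(running, m.a_end)
            self._prefix_max_end.append(running)

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self) -> Iterator[RangeMatch]:
        return iter(self.matches)

    def iter_canonical(self) -> Iterator[RangeMatch]:
        """Each stored pair once (the a_start < b_start orientation)."""
        return (m for m in self.matches if m.a_start < m.b_start)

    def overlapping(self, lo: int, hi: int) -> list[RangeMatch]:
        """All matches whose first range intersects [lo, hi)."""
        if lo >= hi:
            return []
        out: list[RangeMatch] = []
        i = bisect_left(self._starts, hi) - 1
        while i >= 0 and self._prefix_max_end[i] > lo:
            if self.matches[i].a_end > lo:
                out.append(self.matches[i])
            i -= 1
        out.reverse()
        return out

    def matches_at(self, pos: int) -> list[int]:
        """Every partner position paired with pos by some stored match."""
        partners = set()
        for m in self.overlapping(pos, pos + 1):
            p = m.b_start + (pos - m.a_start)
            if p != pos:
                partners.add(p)
        return sorted(partners)


def build_match_index(matches: Iterable[RangeMatch]) -> MatchIndex:
    """Build the symmetric, sorted, deduplicated match index."""
    return MatchIndex(matches)


def matches_from_paf(
    source: Union[str, IO],
    index: SequenceIndex,
    min_match_len: int = 0,
) -> MatchIndex:
    """Convenience: parse a PAF source and build the match index."""
    all_matches: list[RangeMatch] = []
    for rec in parse_paf(source, index):
        all_matches.extend(cigar_to_matches(rec, index, min_match_len))
    return build_match_index(all_matches)
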