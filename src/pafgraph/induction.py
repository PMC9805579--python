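"""Transitive match closure and graph-sequence induction.

Every character of the graph sequence V is the transitive closure of a set
of matched Q positions: positions linked by chains of alignment matches
(and strand mirrors) collapse to a single node character c(m+).  Scanning
forward Q positions in ascending order, each not-yet-seen position seeds a
closure, appends its character to V, and extends the bidirectional range
mappings Z (Q→V) and Z̄ (V→Q).

Two interchangeable mechanisms compute the closures:

* ``method="uf"`` (default): a union-find with an orientation parity bit,
  fed by expanding every canonical range match once.  Fast, and the
  reference mechanism for large inputs.
* ``method="bfs"``: a literal per-position scan that queries the implicit
  interval tree for the matches of one character at a time, marking used
  characters in a seen-bitvector.

Both must produce bit-identical results; a closure is the connected
component of the character-level match graph either way, so the scan order
over Q alone fixes node numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

from .alignments import MatchIndex
from .seqstore import COMPLEMENT, SequenceIndex

__all__ = [
    "SeenBitvector",
    "Closure",
    "ClosureState",
    "ZRange",
    "ClosureConflictError",
    "transitive_closure",
    "induce",
    "invert_mapping",
]

DEFAULT_PARTITION_SIZE = 1_000_000


class ClosureConflictError(ValueError):
    """Two members of one closure carry disagreeing bases under orientation.

    Signals corrupt input, e.g. a CIGAR '=' op over unequal bases.
    """


class SeenBitvector:
    """One bit per forward Q position, set exactly once per character."""

    def __init__(self, size: int):
        self.size = size
        self._bits = bytearray(size)

    def __getitem__(self, pos: int) -> bool:
        return bool(self._bits[pos])

    def mark(self, pos: int) -> None:
        if self._bits[pos]:
            raise ValueError(f"position {pos} absorbed twice")
        self._bits[pos] = 1

    def count(self) -> int:
        return sum(self._bits)

    def all_set(self) -> bool:
        return all(self._bits)


@dataclass
class Closure:
    """One transitive match closure.

    ``members`` maps forward Q positions to their orientation relative to
    the closure's character: a '+' member reads ``character`` on its
    forward strand, a '−' member reads its complement.
    """

    members: dict[int, str]
    character: str


class ZRange(NamedTuple):
    """A range mapping between Q and V (or V and Q).

    ``src_start + t`` maps to ``dst_start + t`` when orient is '+', and to
    ``dst_start + length - 1 - t`` when orient is '−' (the image is read in
    reverse).  The same tuple shape serves both directions; the inverse of
    a mapping is the tuple with src and dst swapped, same orientation.
    """

    src_start: int
    dst_start: int
    length: int
    orient: str

    @property
    def src_end(self) -> int:
        return self.src_start + self.length

    @property
    def dst_end(self) -> int:
        return self.dst_start + self.length


@dataclass
class ClosureState:
    """The induced graph sequence V and its Q↔V range mappings."""

    graph_seq: str
    z_fwd: list[ZRange]  # Q → V, sorted by Q start, tiling [0, |S|)
    z_rev: list[ZRange] = field(default_factory=list)  # V → Q
    _fwd_starts: list[int] | None = field(default=None, repr=False, compare=False)

    def mapping_at(self, pos: int) -> tuple[int, str]:
        """(V position, orientation) of one forward Q position."""
        from bisect import bisect_right

        if self._fwd_starts is None or len(self._fwd_starts) != len(self.z_fwd):
            self._fwd_starts = [r.src_start for r in self.z_fwd]
        starts = self._fwd_starts
        i = bisect_right(starts, pos) - 1
        if i < 0:
            raise ValueError(f"Q position {pos} not covered by any Z range")
        r = self.z_fwd[i]
        if not (r.src_start <= pos < r.src_end):
            raise ValueError(f"Q position {pos} not covered by any Z range")
        t = pos - r.src_start
        v = r.dst_start + t if r.orient == "+" else r.dst_start + r.length - 1 - t
        return v, r.orient


# ---------------------------------------------------------------------------
# BFS closure over interval-tree queries (the per-character mechanism)
# ---------------------------------------------------------------------------


def transitive_closure(
    pos: int,
    matches: MatchIndex,
    seen: SeenBitvector,
    index: SequenceIndex,
) -> Closure:
    """The connected component of ``pos`` in the character match graph.

    Starting from an unseen forward position, repeatedly follows
    ``matches_at`` on both strands of every member (the strand mirror is
    implicit: querying the mirror position covers matches recorded against
    the reverse half of Q).
    """
    n = index.total_length
    if seen[pos]:
        raise ValueError(f"position {pos} already absorbed into a closure")
    character = index.char_at(pos)
    members: dict[int, str] = {pos: "+"}
    stack = [pos]
    while stack:
        f = stack.pop()
        o = members[f]
        p_read = f if o == "+" else index.mirror(f)  # reads `character`
        for p, same_strand_reads_char in ((p_read, True), (index.mirror(p_read), False)):
            for q in matches.matches_at(p):
                if q < n:
                    fq, oq = q, "+"
                else:
                    fq, oq = index.mirror(q), "-"
                if not same_strand_reads_char:
                    oq = "-" if oq == "+" else "+"
                prev = members.get(fq)
                if prev is None:
                    if seen[fq]:
                        raise ValueError(
                            f"closure reached already-seen position {fq}"
                        )
                    members[fq] = oq
                    stack.append(fq)
                elif prev != oq and character != COMPLEMENT[character]:
                    raise ClosureConflictError(
                        f"positions {pos} and {fq} disagree on orientation: "
                        f"character {character!r} would need to equal its "
                        "complement (corrupt input match)"
                    )
    for f, o in members.items():
        expected = character if o == "+" else COMPLEMENT[character]
        if index.sequence[f] != expected:
            raise ClosureConflictError(
                f"positions {pos} and {f} carry disagreeing bases "
                f"({character!r} vs {index.sequence[f]!r} under orientation "
                f"{o!r}): corrupt input match"
            )
    return Closure(members=members, character=character)


# ---------------------------------------------------------------------------
# Orientation-parity union-find (the batch mechanism)
# ---------------------------------------------------------------------------


class _OrientedUnionFind:
    """Union-find over forward positions with a relative-orientation bit.

    ``parity[x]`` is the orientation of x relative to its parent (0 same,
    1 flipped); ``find`` returns (root, parity to root) with path
    compression; unions are by size.
    """

    __slots__ = ("parent", "parity", "size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.parity = bytearray(n)
        self.size = [1] * n

    def find(self, x: int) -> tuple[int, int]:
        parent = self.parent
        parity = self.parity
        root = x
        p = 0
        while parent[root] != root:
            p ^= parity[root]
            root = parent[root]
        result = p  # parity of the queried position relative to root
        # path compression with parity update
        while parent[x] != root:
            nxt = parent[x]
            nxt_p = p ^ parity[x]  # parity of nxt to root via x's old chain
            p_x = p
            parent[x] = root
            parity[x] = p_x
            x = nxt
            p = nxt_p
        return root, result

    def union(self, x: int, y: int, flip: int) -> None:
        rx, px = self.find(x)
        ry, py = self.find(y)
        if rx == ry:
            if (px ^ py) != flip:
                raise ClosureConflictError(
                    f"positions {x} and {y} are matched in both orientations: "
                    "a character would need to equal its own complement "
                    "(corrupt input match)"
                )
            return
        if self.size[rx] < self.size[ry]:
            rx, ry = ry, rx
            px, py = py, px
        self.parent[ry] = rx
        self.parity[ry] = px ^ py ^ flip
        self.size[rx] += self.size[ry]


def _union_all_matches(index: SequenceIndex, matches: MatchIndex) -> _OrientedUnionFind:
    n = index.total_length
    uf = _OrientedUnionFind(n)
    union = uf.union
    mirror = index.mirror
    for a, b, length in matches.iter_canonical():
        # project each range onto the forward strand once; within one
        # sequence block the mirror is an arithmetic reflection, so the
        # per-base loop stays pure integer arithmetic
        if a < n:
            fa, da = a, 1
        else:
            fa, da = mirror(a), -1
        if b < n:
            fb, db = b, 1
        else:
            fb, db = mirror(b), -1
        flip = 1 if da != db else 0
        for t in range(length):
            union(fa + da * t, fb + db * t, flip)
    return uf


# ---------------------------------------------------------------------------
# The induction scan
# ---------------------------------------------------------------------------


class _RunBuilder:
    """Merges consecutive per-position mappings into ZRange runs.

    Runs never span two input sequences: a path step must belong to one
    sequence, so a run is forced to break at every sequence start.
    """

    def __init__(self, seq_starts: frozenset[int] = frozenset()):
        self.ranges: list[ZRange] = []
        self._seq_starts = seq_starts
        self._q0 = self._v0 = self._len = 0
        self._orient = "+"

    def add(self, q: int, v: int, orient: str) -> None:
        if self._len and q in self._seq_starts:
            self.flush()
        if self._len:
            step = 1 if self._orient == "+" else -1
            if (
                orient == self._orient
                and q == self._q0 + self._len
                and v == self._v0 + step * self._len
            ):
                self._len += 1
                return
            self.flush()
        self._q0, self._v0, self._orient, self._len = q, v, orient, 1

    def flush(self) -> None:
        if self._len:
            if self._orient == "+":
                self.ranges.append(ZRange(self._q0, self._v0, self._len, "+"))
            else:
                v_lo = self._v0 - self._len + 1
                self.ranges.append(ZRange(self._q0, v_lo, self._len, "-"))
            self._len = 0


def _merge_ranges(
    ranges: list[ZRange], seq_starts: frozenset[int] = frozenset()
) -> list[ZRange]:
    """Re-merge adjacent compatible ranges (partition boundary repair)."""
    merged: list[ZRange] = []
    for r in ranges:
        if merged and r.src_start not in seq_starts:
            p = merged[-1]
            if p.orient == r.orient == "+" and r.src_start == p.src_end and r.dst_start == p.dst_end:
                merged[-1] = ZRange(p.src_start, p.dst_start, p.length + r.length, "+")
                continue
            if (
                p.orient == r.orient == "-"
                and r.src_start == p.src_end
                and r.dst_end == p.dst_start
            ):
                merged[-1] = ZRange(p.src_start, r.dst_start, p.length + r.length, "-")
                continue
        merged.append(r)
    return merged


def invert_mapping(z_fwd: list[ZRange]) -> list[ZRange]:
    """The exact inverse image Z̄ (V→Q), sorted by V position."""
    return sorted(ZRange(r.dst_start, r.src_start, r.length, r.orient) for r in z_fwd)


def induce(
    index: SequenceIndex,
    matches: MatchIndex,
    partition_size: int = DEFAULT_PARTITION_SIZE,
    method: str = "uf",
) -> ClosureState:
    """Scan forward Q ascending, emitting V and the Z / Z̄ range mappings.

    ``partition_size`` bounds the span of scan positions whose mappings are
    held un-compressed at once; ranges are flushed per partition and
    re-merged in a final pass, so the choice cannot change ``graph_seq``
    nor the character-level content of Z.
    """
    if partition_size < 1:
        raise ValueError("partition_size must be >= 1")
    if method not in ("uf", "bfs"):
        raise ValueError(f"unknown induction method {method!r}")
    n = index.total_length
    seq = index.sequence
    seq_starts = frozenset(r.offset for r in index.records)
    graph_chars: list[str] = []
    ranges: list[ZRange] = []

    if method == "uf":
        uf = _union_all_matches(index, matches)
        find = uf.find
        comp_node: dict[int, tuple[int, int]] = {}  # root -> (v, seed parity)
        for chunk_start in range(0, n, partition_size):
            run = _RunBuilder(seq_starts)
            for i in range(chunk_start, min(chunk_start + partition_size, n)):
                root, par = find(i)
                entry = comp_node.get(root)
                if entry is None:
                    entry = (len(graph_chars), par)
                    comp_node[root] = entry
                    graph_chars.append(seq[i])
                v, seed_par = entry
                if par == seed_par:
                    orient = "+"
                    expected = graph_chars[v]
                else:
                    orient = "-"
                    expected = COMPLEMENT[graph_chars[v]]
                if seq[i] != expected:
                    raise ClosureConflictError(
                        f"position {i} carries base {seq[i]!r} but its closure "
                        f"character is {graph_chars[v]!r} (orientation {orient!r}): "
                        "corrupt input match"
                    )
                run.add(i, v, orient)
            run.flush()
            ranges.extend(run.ranges)
    else:
        seen = SeenBitvector(n)
        pos_map: dict[int, tuple[int, str]] = {}
        for chunk_start in range(0, n, partition_size):
            run = _RunBuilder(seq_starts)
            for i in range(chunk_start, min(chunk_start + partition_size, n)):
                if not seen[i]:
                    closure = transitive_closure(i, matches, seen, index)
                    v = len(graph_chars)
                    graph_chars.append(closure.character)
                    for f, o in closure.members.items():
                        seen.mark(f)
                        pos_map[f] = (v, o)
                v, orient = pos_map.pop(i)
                run.add(i, v, orient)
            run.flush()
            ranges.extend(run.ranges)

    z_fwd = _merge_ranges(ranges, seq_starts)
    state = ClosureState(graph_seq="".join(graph_chars), z_fwd=z_fwd)
    state.z_rev = invert_mapping(z_fwd)
    return state
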