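"""Node compaction: collapse identically-traversed runs of V into nodes.

A boundary bitvector B (one bit per V position) marks the first character
of each compacted node; node ids are 1-based ranks of set bits, so the id
of the node containing V position i is rank(i+1).  A boundary is placed at
V position 0 and at the image in V of every Z range start and one-past-end.
Because the Z ranges are maximal after the final re-merge, the set of Z̄
ranges overlapping position i changes exactly at those images, so this
endpoint rule coincides with detecting overlap-set changes while also
guaranteeing that every path step begins and ends on a node boundary.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable

from .induction import ClosureState

__all__ = ["BoundaryBitvector", "CompactNode", "mark_boundaries", "compact", "node_of"]


class BoundaryBitvector:
    """Sorted set of boundary positions over [0, size) with rank support."""

    def __init__(self, size: int, positions: Iterable[int]):
        self.size = size
        self.positions = sorted(set(positions))
        for p in self.positions:
            if not 0 <= p < size:
                raise ValueError(f"boundary {p} outside [0, {size})")
        if size > 0 and (not self.positions or self.positions[0] != 0):
            raise ValueError("position 0 must be a boundary of a non-empty V")

    def __len__(self) -> int:
        return self.size

    def is_set(self, i: int) -> bool:
        j = bisect_left(self.positions, i)
        return j < len(self.positions) and self.positions[j] == i

    def rank(self, i: int) -> int:
        """Number of set bits in [0, i)."""
        if not 0 <= i <= self.size:
            raise IndexError(f"rank position {i} outside [0, {self.size}]")
        return bisect_left(self.positions, i)

    def node_count(self) -> int:
        return len(self.positions)

    def node_span(self, node_id: int) -> tuple[int, int]:
        """Half-open V range of a 1-based node id."""
        if not 1 <= node_id <= len(self.positions):
            raise IndexError(f"no node with id {node_id}")
        start = self.positions[node_id - 1]
        end = self.positions[node_id] if node_id < len(self.positions) else self.size
        return start, end

    def segments_in(self, lo: int, hi: int) -> list[tuple[int, int]]:
        """Split [lo, hi) at internal boundaries into node-aligned pieces."""
        cuts = [lo]
        i = bisect_right(self.positions, lo)
        while i < len(self.positions) and self.positions[i] < hi:
            cuts.append(self.positions[i])
            i += 1
        cuts.append(hi)
        return [(cuts[k], cuts[k + 1]) for k in range(len(cuts) - 1)]


@dataclass(frozen=True)
class CompactNode:
    """One compacted node: a boundary-delimited run of V."""

    id: int  # 1-based, ascending in V order
    sequence: str
    v_start: int
    v_end: int


def mark_boundaries(state: ClosureState) -> BoundaryBitvector:
    """Boundary bitvector over V from the Z̄ range images."""
    size = len(state.graph_seq)
    positions = set()
    if size:
        positions.add(0)
    for r in state.z_fwd:
        positions.add(r.dst_start)
        if r.dst_end < size:
            positions.add(r.dst_end)
    return BoundaryBitvector(size, positions)


def compact(state: ClosureState, bounds: BoundaryBitvector) -> list[CompactNode]:
    """One node per boundary-delimited run, ids assigned by rank."""
    v = state.graph_seq
    nodes = []
    for node_id in range(1, bounds.node_count() + 1):
        start, end = bounds.node_span(node_id)
        nodes.append(CompactNode(node_id, v[start:end], start, end))
    return nodes


def node_of(bounds: BoundaryBitvector, v_pos: int) -> tuple[int, int]:
    """(node id, offset within node) of a V position."""
    if not 0 <= v_pos < bounds.size:
        raise IndexError(f"V position {v_pos} outside [0, {bounds.size})")
    node_id = bounds.rank(v_pos + 1)
    start, _ = bounds.node_span(node_id)
    return node_id, v_pos - start
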