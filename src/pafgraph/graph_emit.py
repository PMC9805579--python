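"""Path tracing, edge derivation and GFA v1 emission.

Each input sequence is walked through its Z ranges in Q order; each range's
V image is split at node boundaries and emitted as oriented node steps
(reverse-mapped ranges yield '−' steps in reversed segment order).  The
edge set is the canonicalized collection of consecutive step pairs across
all paths; an edge and its reverse-complement image are one record.
Output is GFA v1.0 with H/S/L/P records in a byte-deterministic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, NamedTuple, Union

from .compaction import BoundaryBitvector, CompactNode, compact, mark_boundaries
from .induction import ClosureState
from .seqstore import SequenceIndex, revcomp

__all__ = [
    "PathStep",
    "Edge",
    "VariationGraph",
    "trace_paths",
    "derive_edges",
    "write_gfa",
    "read_gfa",
    "build_graph",
]


class PathStep(NamedTuple):
    """An oriented traversal of one node."""

    node_id: int
    orient: str  # '+' or '-'

    def flipped(self) -> "PathStep":
        return PathStep(self.node_id, "-" if self.orient == "+" else "+")


def _step_key(s: PathStep) -> tuple[int, int]:
    return (s.node_id, 0 if s.orient == "+" else 1)


class Edge(NamedTuple):
    """A canonical link between two node strands.

    An edge (a, b) and its reverse-complement image (rc(b), rc(a)) denote
    the same adjacency; the stored form is the lexicographically smaller
    of the two under (id, orientation) ordering.
    """

    from_step: PathStep
    to_step: PathStep

    @staticmethod
    def canonical(a: PathStep, b: PathStep) -> "Edge":
        fwd = (a, b)
        rc = (b.flipped(), a.flipped())
        chosen = min(fwd, rc, key=lambda e: (_step_key(e[0]), _step_key(e[1])))
        return Edge(*chosen)


@dataclass
class VariationGraph:
    """The final bidirected sequence graph G = (V', E, P)."""

    nodes: list[CompactNode]
    edges: set[Edge]
    paths: dict[str, list[PathStep]]  # insertion order = input order

    def node(self, node_id: int) -> CompactNode:
        return self.nodes[node_id - 1]

    @property
    def length(self) -> int:
        return sum(len(n.sequence) for n in self.nodes)

    def path_sequence(self, name: str) -> str:
        """Spell a path: node sequences, reverse-complemented on '−'."""
        parts = []
        for step in self.paths[name]:
            s = self.node(step.node_id).sequence
            parts.append(s if step.orient == "+" else revcomp(s))
        return "".join(parts)


def trace_paths(
    index: SequenceIndex,
    state: ClosureState,
    bounds: BoundaryBitvector,
) -> dict[str, list[PathStep]]:
    """Walk each input sequence through Z, one oriented step per node."""
    paths: dict[str, list[PathStep]] = {}
    z = state.z_fwd
    zi = 0
    for rec in index.records:
        steps: list[PathStep] = []
        pos = rec.offset
        while pos < rec.end:
            if zi >= len(z) or not (z[zi].src_start <= pos < z[zi].src_end):
                raise ValueError(
                    f"Q position {pos} of {rec.name!r} is not covered by Z "
                    "(induction was not exhaustive)"
                )
            r = z[zi]
            if r.src_end > rec.end:
                raise ValueError(
                    f"Z range {r} crosses the boundary of {rec.name!r}"
                )
            segments = bounds.segments_in(r.dst_start, r.dst_end)
            if r.orient == "+":
                for s, _e in segments:
                    node_id = bounds.rank(s + 1)
                    steps.append(PathStep(node_id, "+"))
            else:
                for s, _e in reversed(segments):
                    node_id = bounds.rank(s + 1)
                    steps.append(PathStep(node_id, "-"))
            pos = r.src_end
            zi += 1
        paths[rec.name] = steps
    return paths


def derive_edges(paths: dict[str, list[PathStep]]) -> set[Edge]:
    """Canonicalized unique consecutive step pairs across all paths."""
    edges: set[Edge] = set()
    for steps in paths.values():
        for a, b in zip(steps, steps[1:]):
            edges.add(Edge.canonical(a, b))
    return edges


def build_graph(index: SequenceIndex, state: ClosureState) -> VariationGraph:
    """Compact, trace and link: the full graph from a closure state."""
    bounds = mark_boundaries(state)
    nodes = compact(state, bounds)
    paths = trace_paths(index, state, bounds)
    edges = derive_edges(paths)
    return VariationGraph(nodes=nodes, edges=edges, paths=paths)


# ---------------------------------------------------------------------------
# GFA v1 I/O
# ---------------------------------------------------------------------------


def _edge_sort_key(e: Edge):
    return (_step_key(e.from_step), _step_key(e.to_step))


def write_gfa(graph: VariationGraph, sink: Union[str, IO]) -> None:
    """Write GFA v1.0: H, S ascending by id, L in canonical order, P in
    input-sequence order; L overlaps are 0M, P overlaps are '*'."""
    own = False
    if not hasattr(sink, "write"):
        sink = open(sink, "w")
        own = True
    try:
        sink.write("H\tVN:Z:1.0\n")
        for node in graph.nodes:
            sink.write(f"S\t{node.id}\t{node.sequence}\n")
        for e in sorted(graph.edges, key=_edge_sort_key):
            sink.write(
                f"L\t{e.from_step.node_id}\t{e.from_step.orient}"
                f"\t{e.to_step.node_id}\t{e.to_step.orient}\t0M\n"
            )
        for name, steps in graph.paths.items():
            walk = ",".join(f"{s.node_id}{s.orient}" for s in steps)
            sink.write(f"P\t{name}\t{walk}\t*\n")
    finally:
        if own:
            sink.close()


def read_gfa(source: Union[str, IO]) -> VariationGraph:
    """Parse S/L/P records back into a VariationGraph."""
    own = False
    if not hasattr(source, "read"):
        source = open(source, "r")
        own = True
    try:
        seqs: dict[int, str] = {}
        links: list[tuple[PathStep, PathStep]] = []
        paths: dict[str, list[PathStep]] = {}
        for lineno, line in enumerate(source, start=1):
            line = line.rstrip("\n")
            if not line or line[0] == "H":
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise ValueError(f"GFA line {lineno}: malformed S record")
                seqs[int(fields[1])] = fields[2]
            elif tag == "L":
                if len(fields) < 5:
                    raise ValueError(f"GFA line {lineno}: malformed L record")
                links.append(
                    (
                        PathStep(int(fields[1]), fields[2]),
                        PathStep(int(fields[3]), fields[4]),
                    )
                )
            elif tag == "P":
                if len(fields) < 3:
                    raise ValueError(f"GFA line {lineno}: malformed P record")
                steps = []
                for token in fields[2].split(","):
                    if not token or token[-1] not in "+-":
                        raise ValueError(
                            f"GFA line {lineno}: malformed path step {token!r}"
                        )
                    steps.append(PathStep(int(token[:-1]), token[-1]))
                paths[fields[1]] = steps
            else:
                raise ValueError(f"GFA line {lineno}: unknown record type {tag!r}")
        nodes = []
        v = 0
        for node_id in sorted(seqs):
            s = seqs[node_id]
            nodes.append(CompactNode(node_id, s, v, v + len(s)))
            v += len(s)
        edges = {Edge.canonical(a, b) for a, b in links}
        return VariationGraph(nodes=nodes, edges=edges, paths=paths)
    finally:
        if own:
            source.close()
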