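"""pafgraph: lossless pangenome variation graph induction.

Builds a variation graph G = (V, E, P) from a FASTA of input sequences and
a PAF of pairwise alignments with base-level CIGARs, such that every input
sequence is embedded as a path that spells it exactly and every alignment
match is embedded as a shared node.
"""

from __future__ import annotations

from typing import IO, Union

from .alignments import (
    MatchIndex,
    PafRecord,
    RangeMatch,
    build_match_index,
    cigar_to_matches,
    matches_from_paf,
    parse_paf,
)
from .compaction import BoundaryBitvector, CompactNode, compact, mark_boundaries, node_of
from .graph_emit import (
    Edge,
    PathStep,
    VariationGraph,
    build_graph,
    derive_edges,
    read_gfa,
    trace_paths,
    write_gfa,
)
from .induction import (
    Closure,
    ClosureConflictError,
    ClosureState,
    SeenBitvector,
    ZRange,
    induce,
    invert_mapping,
    transitive_closure,
)
from .seqstore import SequenceIndex, SequenceRecord, load_sequences, revcomp

__version__ = "0.1.0"

__all__ = [
    "induce_graph",
    "load_sequences",
    "parse_paf",
    "cigar_to_matches",
    "build_match_index",
    "matches_from_paf",
    "induce",
    "transitive_closure",
    "invert_mapping",
    "mark_boundaries",
    "compact",
    "node_of",
    "trace_paths",
    "derive_edges",
    "build_graph",
    "write_gfa",
    "read_gfa",
    "SequenceIndex",
    "SequenceRecord",
    "PafRecord",
    "RangeMatch",
    "MatchIndex",
    "SeenBitvector",
    "Closure",
    "ClosureState",
    "ClosureConflictError",
    "ZRange",
    "BoundaryBitvector",
    "CompactNode",
    "PathStep",
    "Edge",
    "VariationGraph",
    "revcomp",
]


def induce_graph(
    fasta: Union[str, IO],
    paf: Union[str, IO],
    min_match_len: int = 0,
    partition_size: int = 1_000_000,
    method: str = "uf",
) -> VariationGraph:
    """End-to-end induction: FASTA + PAF → compacted variation graph."""
    index = load_sequences(fasta)
    matches = matches_from_paf(paf, index, min_match_len)
    state = induce(index, matches, partition_size=partition_size, method=method)
    return build_graph(index, state)
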