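import io

import pytest

from pafgraph import load_sequences, matches_from_paf, induce, build_graph


@pytest.fixture
def two_seq_fixture():
    """The hand-worked ACGT/ACTT pair with match runs (0-2) and (3-4)."""
    fasta = ">seq1\nACGT\n>seq2\nACTT\n"
    paf = "seq1\t4\t0\t4\t+\tseq2\t4\t0\t4\t2\t4\t60\tcg:Z:2=1X1=\n"
    return fasta, paf


def build_pipeline(fasta_text: str, paf_text: str, k: int = 0, **induce_kw):
    """Run the full pipeline from in-memory text; returns (index, state, graph)."""
    index = load_sequences(io.StringIO(fasta_text))
    matches = matches_from_paf(io.StringIO(paf_text), index, k)
    state = induce(index, matches, **induce_kw)
    graph = build_graph(index, state)
    return index, state, graph
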