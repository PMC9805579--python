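import io

import pytest

from pafgraph import (
    ClosureConflictError,
    SeenBitvector,
    ZRange,
    induce,
    invert_mapping,
    load_sequences,
    matches_from_paf,
    transitive_closure,
)
from pafgraph.alignments import build_match_index

from conftest import build_pipeline
from oracles import closure_partition


def _setup(fasta, paf, k=0):
    idx = load_sequences(io.StringIO(fasta))
    return idx, matches_from_paf(io.StringIO(paf), idx, k)


def _partition_from_state(idx, state):
    groups = {}
    for p in range(idx.total_length):
        v, _ = state.mapping_at(p)
        groups.setdefault(v, []).append(p)
    return {frozenset(g) for g in groups.values()}


def test_isolated_character_closure():
    idx, matches = _setup(">a\nACGT\n", "")
    seen = SeenBitvector(4)
    c = transitive_closure(0, matches, seen, idx)
    assert c.members == {0: "+"}
    assert c.character == "A"


def test_transitivity_links_unaligned_pair():
    """seq1~seq2 and seq1~seq3 matches imply a seq2~seq3 relationship."""
    fasta = ">seq1\nACGT\n>seq2\nACGT\n>seq3\nACGT\n"
    paf = (
        "seq1\t4\t0\t4\t+\tseq2\t4\t0\t4\t4\t4\t60\tcg:Z:4=\n"
        "seq1\t4\t0\t4\t+\tseq3\t4\t0\t4\t4\t4\t60\tcg:Z:4=\n"
    )
    idx, matches = _setup(fasta, paf)
    seen = SeenBitvector(idx.total_length)
    c = transitive_closure(0, matches, seen, idx)
    # one closure holds the first character of all three sequences
    assert set(c.members) == {0, 4, 8}
    assert all(o == "+" for o in c.members.values())


def test_closure_conflict_on_corrupt_equal_op():
    # '=' asserts identity over unequal bases A vs C
    idx, matches = _setup(
        ">a\nAAAA\n>b\nCCCC\n",
        "a\t4\t0\t4\t+\tb\t4\t0\t4\t4\t4\t60\tcg:Z:4=\n",
    )
    with pytest.raises(ClosureConflictError, match="corrupt input"):
        induce(idx, matches)
    seen = SeenBitvector(idx.total_length)
    with pytest.raises(ClosureConflictError):
        transitive_closure(0, matches, seen, idx)


def test_induce_perfect_merge():
    idx, matches = _setup(
        ">a\nACGT\n>b\nACGT\n",
        "a\t4\t0\t4\t+\tb\t4\t0\t4\t4\t4\t60\tcg:Z:4=\n",
    )
    state = induce(idx, matches)
    assert state.graph_seq == "ACGT"
    assert state.z_fwd == [ZRange(0, 0, 4, "+"), ZRange(4, 0, 4, "+")]


def test_induce_disjoint_union():
    idx, matches = _setup(">a\nAC\n>b\nGT\n", "")
    state = induce(idx, matches)
    assert state.graph_seq == "ACGT"
    assert state.z_fwd == [ZRange(0, 0, 2, "+"), ZRange(2, 2, 2, "+")]


def test_induce_hand_run_acgt_actt(two_seq_fixture):
    idx, state, _ = build_pipeline(*two_seq_fixture)
    # scan order: shared A, C; private G; shared T; then seq2's private T
    assert state.graph_seq == "ACGTT"
    assert state.mapping_at(6) == (4, "+")  # seq2's private T
    assert state.mapping_at(7) == (3, "+")  # shared final T


def test_inverted_alignment_gives_reverse_mapping():
    # b is the reverse complement of a, aligned on the minus strand
    fasta = ">a\nACGTA\n>b\nTACGT\n"
    paf = "a\t5\t0\t5\t-\tb\t5\t0\t5\t5\t5\t60\tcg:Z:5=\n"
    idx, matches = _setup(fasta, paf)
    state = induce(idx, matches)
    assert state.graph_seq == "ACGTA"
    assert state.z_fwd == [ZRange(0, 0, 5, "+"), ZRange(5, 0, 5, "-")]
    # b's path must still spell b
    v, o = state.mapping_at(5)
    assert (v, o) == (4, "-")


def test_bfs_and_union_find_routes_agree(two_seq_fixture):
    from pafgraph.fixtures import MutationModel, simulate_pangenome, truth_to_paf

    cases = [two_seq_fixture]
    truth = simulate_pangenome(
        300, 3, MutationModel(snp_rate=0.02, indel_rate=0.003,
                              inversion_count=1, inversion_length=(30, 60), seed=9)
    )
    cases.append((truth.fasta_text(), truth_to_paf(truth)))
    for fasta, paf in cases:
        idx, matches = _setup(fasta, paf)
        a = induce(idx, matches, method="uf")
        b = induce(idx, matches, method="bfs")
        assert a.graph_seq == b.graph_seq
        assert a.z_fwd == b.z_fwd
        assert a.z_rev == b.z_rev


def test_closures_match_exhaustive_character_oracle():
    from pafgraph.fixtures import MutationModel, simulate_pangenome, truth_to_paf

    for seed in (1, 2, 3):
        truth = simulate_pangenome(
            250, 3, MutationModel(snp_rate=0.02, indel_rate=0.002,
                                  inversion_count=1, inversion_length=(20, 40),
                                  seed=seed)
        )
        fasta, paf = truth.fasta_text(), truth_to_paf(truth)
        idx, state, _ = build_pipeline(fasta, paf)
        assert _partition_from_state(idx, state) == closure_partition(fasta, paf)


def test_partition_size_does_not_change_result():
    from pafgraph.fixtures import MutationModel, simulate_pangenome, truth_to_paf

    truth = simulate_pangenome(400, 3, MutationModel(seed=21))
    idx, matches = _setup(truth.fasta_text(), truth_to_paf(truth))
    ref = induce(idx, matches, partition_size=idx.total_length)
    for ps in (1, 100, 997):
        got = induce(idx, matches, partition_size=ps)
        assert got.graph_seq == ref.graph_seq
        assert got.z_fwd == ref.z_fwd


def test_alignment_record_order_is_irrelevant():
    fasta = ">a\nACGTACGT\n>b\nACGAACGT\n>c\nACGTACGA\n"
    lines = [
        "a\t8\t0\t8\t+\tb\t8\t0\t8\t7\t8\t60\tcg:Z:3=1X4=",
        "a\t8\t0\t8\t+\tc\t8\t0\t8\t7\t8\t60\tcg:Z:7=1X",
        "b\t8\t0\t8\t+\tc\t8\t0\t8\t6\t8\t60\tcg:Z:3=1X3=1X",
    ]
    ref = None
    for order in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
        paf = "".join(lines[i] + "\n" for i in order)
        idx, matches = _setup(fasta, paf)
        state = induce(idx, matches)
        if ref is None:
            ref = state
        else:
            assert state.graph_seq == ref.graph_seq
            assert state.z_fwd == ref.z_fwd


def test_every_position_covered_exactly_once():
    from pafgraph.fixtures import MutationModel, simulate_pangenome, truth_to_paf

    truth = simulate_pangenome(300, 4, MutationModel(snp_rate=0.01, seed=17))
    idx, state, _ = build_pipeline(truth.fasta_text(), truth_to_paf(truth))
    covered = sorted(
        p for r in state.z_fwd for p in range(r.src_start, r.src_end)
    )
    assert covered == list(range(idx.total_length))


def test_invert_mapping_roundtrip():
    z = [ZRange(0, 0, 4, "+"), ZRange(4, 0, 4, "+"), ZRange(8, 2, 3, "-")]
    zr = invert_mapping(z)
    assert zr == sorted(ZRange(r.dst_start, r.src_start, r.length, r.orient) for r in z)
    # composing forward then inverse returns each position to itself
    for r in z:
        for t in range(r.length):
            q = r.src_start + t
            v = r.dst_start + t if r.orient == "+" else r.dst_start + r.length - 1 - t
            back = set()
            for rr in zr:
                if rr.src_start <= v < rr.src_end:
                    u = v - rr.src_start
                    back.add(
                        rr.dst_start + u
                        if rr.orient == "+"
                        else rr.dst_start + rr.length - 1 - u
                    )
            assert q in back


def test_seen_bitvector_single_absorption():
    bv = SeenBitvector(4)
    bv.mark(2)
    assert bv[2] and not bv[0]
    with pytest.raises(ValueError, match="twice"):
        bv.mark(2)
    assert bv.count() == 1 and not bv.all_set()
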