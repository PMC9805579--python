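import io
import random

import pytest
from hypothesis import given, settings, strategies as st

from pafgraph.alignments import (
    MatchIndex,
    RangeMatch,
    build_match_index,
    cigar_to_matches,
    parse_paf,
)
from pafgraph.seqstore import SequenceIndex

from oracles import QSpace, expand_paf_char_pairs, parse_fasta_text


def _one_record(line: str, index=None):
    return next(parse_paf(io.StringIO(line), index))


def test_parse_minimal_record():
    rec = _one_record("q\t4\t0\t4\t+\tt\t4\t0\t4\t60\t4\t4\tcg:Z:4=\n")
    assert (rec.strand, rec.cigar) == ("+", "4=")
    assert (rec.query_start, rec.target_end) == (0, 4)


def test_parse_minus_strand_record():
    rec = _one_record("q\t4\t0\t4\t-\tt\t4\t0\t4\t60\t4\t4\tcg:Z:4=\n")
    assert rec.strand == "-"


@pytest.mark.parametrize(
    "line,msg",
    [
        ("q\t4\t0\t4\t+\tt\t4\t0\t4\t60\t4\t4", "missing cg:Z"),
        ("q\t4\t0\t4\t+\tt\t4\t0\t4\t60\t4\t4\tcg:Z:3=", "consumes"),
        ("q\t4\t0\t4\t+\tt\t4\t0\t4\t60\t4\t4\tcg:Z:4H", "unsupported CIGAR op"),
        ("q\t4\t4\t0\t+\tt\t4\t0\t4\t60\t4\t4\tcg:Z:4=", "invalid"),
        ("q\t4\t0\t4\t*\tt\t4\t0\t4\t60\t4\t4\tcg:Z:4=", "strand"),
        ("too\tfew", "12 columns"),
    ],
)
def test_malformed_paf_rejected(line, msg):
    with pytest.raises(ValueError, match=msg):
        _one_record(line)


def test_unknown_name_and_length_mismatch_rejected():
    idx = SequenceIndex(["q"], ["ACGT"])
    with pytest.raises(ValueError, match="unknown sequence"):
        _one_record("q\t4\t0\t4\t+\tzzz\t4\t0\t4\t60\t4\t4\tcg:Z:4=", idx)
    idx2 = SequenceIndex(["q", "t"], ["ACGT", "ACGTT"])
    with pytest.raises(ValueError, match="disagrees"):
        _one_record("q\t4\t0\t4\t+\tt\t4\t0\t4\t60\t4\t4\tcg:Z:4=", idx2)


def test_paf_write_parse_roundtrip():
    rnd = random.Random(3)
    lines = []
    for _ in range(20):
        n = rnd.randint(2, 30)
        lines.append(
            f"s{rnd.randint(0, 5)}\t{n + 4}\t2\t{n + 2}\t{rnd.choice('+-')}\t"
            f"s{rnd.randint(0, 5)}\t{n + 4}\t1\t{n + 1}\t{n}\t{n}\t60\tcg:Z:{n}="
        )
    text = "\n".join(lines) + "\n"
    recs = list(parse_paf(io.StringIO(text)))
    assert "\n".join(r.to_paf_line() for r in recs) + "\n" == text


# -- cigar_to_matches --------------------------------------------------------


def _idx_pair(q="AAATAA", t="AAAGAA"):
    return SequenceIndex(["q", "t"], [q, t])


def test_match_runs_split_at_mismatch():
    idx = _idx_pair()
    rec = _one_record("q\t6\t0\t6\t+\tt\t6\t0\t6\t5\t6\t60\tcg:Z:3=1X2=", idx)
    ms = cigar_to_matches(rec, idx, 0)
    # local coordinates: (0,0,3) and (4,4,2); target offset in Q is 6
    assert ms == [RangeMatch(0, 6, 3), RangeMatch(4, 10, 2)]


def test_k_filter_drops_short_runs():
    idx = _idx_pair()
    rec = _one_record("q\t6\t0\t6\t+\tt\t6\t0\t6\t5\t6\t60\tcg:Z:3=1X2=", idx)
    assert [m.length for m in cigar_to_matches(rec, idx, 3)] == [3]
    assert cigar_to_matches(rec, idx, 4) == []


def test_single_run():
    idx = SequenceIndex(["q", "t"], ["ACGTA", "ACGTA"])
    rec = _one_record("q\t5\t0\t5\t+\tt\t5\t0\t5\t5\t5\t60\tcg:Z:5=", idx)
    assert cigar_to_matches(rec, idx, 0) == [RangeMatch(0, 5, 5)]


def test_perfect_self_match_emits_nothing():
    idx = SequenceIndex(["q"], ["ACGTA"])
    rec = _one_record("q\t5\t0\t5\t+\tq\t5\t0\t5\t5\t5\t60\tcg:Z:5=", idx)
    assert cigar_to_matches(rec, idx, 0) == []


def test_M_ops_are_verified_and_split_like_X():
    idx = _idx_pair("AAATAA", "AAAGAA")  # differ at position 3
    rec = _one_record("q\t6\t0\t6\t+\tt\t6\t0\t6\t5\t6\t60\tcg:Z:6M", idx)
    assert cigar_to_matches(rec, idx, 0) == [RangeMatch(0, 6, 3), RangeMatch(4, 10, 2)]


def test_minus_strand_matches_are_identical_under_char_at():
    # t reverse-complements to q exactly
    idx = SequenceIndex(["q", "t"], ["ACGTT", "AACGT"])
    rec = _one_record("q\t5\t0\t5\t-\tt\t5\t0\t5\t5\t5\t60\tcg:Z:5=", idx)
    (m,) = cigar_to_matches(rec, idx, 0)
    assert m.b_start >= idx.total_length  # target range in the reverse half
    for t in range(m.length):
        assert idx.char_at(m.a_start + t) == idx.char_at(m.b_start + t)


def test_indels_advance_without_matching():
    idx = SequenceIndex(["q", "t"], ["AATTAA", "AAAA"])
    rec = _one_record("q\t6\t0\t6\t+\tt\t4\t0\t4\t4\t6\t60\tcg:Z:2=2I2=", idx)
    assert cigar_to_matches(rec, idx, 0) == [RangeMatch(0, 6, 2), RangeMatch(4, 8, 2)]


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_expansion_fidelity_against_per_base_oracle(seed):
    """Range matches expand to exactly the oracle's character pairs."""
    from pafgraph.fixtures import MutationModel, simulate_pangenome, truth_to_paf

    model = MutationModel(snp_rate=0.02, indel_rate=0.002, inversion_count=1,
                          inversion_length=(20, 50), seed=seed)
    truth = simulate_pangenome(200, 2, model)
    fasta, paf = truth.fasta_text(), truth_to_paf(truth)
    idx = SequenceIndex([h.name for h in truth.haplotypes],
                        [h.seq for h in truth.haplotypes])
    got = set()
    for rec in parse_paf(io.StringIO(paf), idx):
        for m in cigar_to_matches(rec, idx, 0):
            for t in range(m.length):
                got.add((m.a_start + t, m.b_start + t))
    q = QSpace(parse_fasta_text(fasta))
    expected = set(expand_paf_char_pairs(paf, q))
    assert got == expected


def test_k_monotonicity_is_subset():
    from pafgraph.fixtures import MutationModel, simulate_pangenome, truth_to_paf

    truth = simulate_pangenome(500, 3, MutationModel(snp_rate=0.03, seed=5))
    idx = SequenceIndex([h.name for h in truth.haplotypes],
                        [h.seq for h in truth.haplotypes])
    paf = truth_to_paf(truth)
    all_matches = {}
    for k in (0, 7, 15):
        ms = []
        for rec in parse_paf(io.StringIO(paf), idx):
            ms.extend(cigar_to_matches(rec, idx, k))
        all_matches[k] = set(ms)
    assert all_matches[15] <= all_matches[7] <= all_matches[0]


# -- MatchIndex --------------------------------------------------------------


def test_index_stores_both_directions_and_dedupes():
    m = RangeMatch(0, 10, 3)
    idx = build_match_index([m, m])
    assert len(idx) == 2
    assert idx.matches_at(1) == [11]
    assert idx.matches_at(11) == [1]
    assert idx.matches_at(5) == []


def test_empty_index():
    idx = build_match_index([])
    assert len(idx) == 0
    assert idx.matches_at(0) == []
    assert idx.overlapping(0, 100) == []


def _random_matches(rnd, n, span=200):
    out = []
    for _ in range(n):
        a = rnd.randrange(span)
        b = rnd.randrange(span)
        length = rnd.randint(1, 10)
        if a != b:
            out.append(RangeMatch(a, b, length))
    return out


def test_overlap_queries_agree_with_linear_scan_and_intervaltree():
    from intervaltree import IntervalTree

    rnd = random.Random(11)
    matches = _random_matches(rnd, 1000)
    idx = build_match_index(matches)
    tree = IntervalTree()
    for m in idx:
        tree.addi(m.a_start, m.a_end, m)
    for _ in range(300):
        lo = rnd.randrange(220)
        hi = lo + rnd.randint(1, 30)
        got = idx.overlapping(lo, hi)
        naive = [m for m in idx if m.a_start < hi and m.a_end > lo]
        assert got == sorted(naive)
        assert {iv.data for iv in tree.overlap(lo, hi)} == set(naive)


def test_matches_at_agrees_with_full_expansion():
    rnd = random.Random(13)
    matches = _random_matches(rnd, 200, span=100)
    idx = build_match_index(matches)
    expanded = {}
    for m in idx:
        for t in range(m.length):
            expanded.setdefault(m.a_start + t, set()).add(m.b_start + t)
    for pos in range(250):
        expected = sorted(p for p in expanded.get(pos, set()) if p != pos)
        assert idx.matches_at(pos) == expected
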