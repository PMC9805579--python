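"""Independent brute-force oracles used to check the pipeline.

Everything here is deliberately self-contained: a minimal FASTA parser, a
per-base CIGAR walker over raw PAF text and a plain dict-based union-find,
sharing no code with the package beyond the text formats themselves.
"""

from __future__ import annotations

import re

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def parse_fasta_text(text: str) -> dict[str, str]:
    """name → sequence, preserving order."""
    seqs: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name is not None and line.strip():
            seqs[name] += line.strip().upper()
    return seqs


class QSpace:
    """Coordinates over S and its implicit reverse complement."""

    def __init__(self, seqs: dict[str, str]):
        self.offsets: dict[str, int] = {}
        self.lengths: dict[str, int] = {}
        s = []
        off = 0
        for name, seq in seqs.items():
            self.offsets[name] = off
            self.lengths[name] = len(seq)
            s.append(seq)
            off += len(seq)
        self.S = "".join(s)
        self.n = off
        self._rec_at = []  # (offset, length) per position, for mirror
        for name, seq in seqs.items():
            self._rec_at.extend([(self.offsets[name], len(seq))] * len(seq))

    def mirror(self, pos: int) -> int:
        if pos < self.n:
            off, length = self._rec_at[pos]
            return self.n + off + (length - 1 - (pos - off))
        rel = pos - self.n
        off, length = self._rec_at[rel]
        return off + (length - 1 - (rel - off))

    def char(self, pos: int) -> str:
        if pos < self.n:
            return self.S[pos]
        return _COMP[self.S[self.mirror(pos)]]


_CIG = re.compile(r"(\d+)([MIDNSHP=X])")


def expand_paf_char_pairs(
    paf_text: str, q: QSpace, min_match_len: int = 0
) -> list[tuple[int, int]]:
    """Every matched character pair (Q positions) from raw PAF text.

    Walks each CIGAR base by base; 'M' pairs count as matches only when the
    characters agree; maximal equal runs shorter than min_match_len are
    discarded whole.
    """
    pairs: list[tuple[int, int]] = []
    for line in paf_text.splitlines():
        if not line:
            continue
        f = line.split("\t")
        qname, qs = f[0], int(f[2])
        strand = f[4]
        tname, tlen, ts, te = f[5], int(f[6]), int(f[7]), int(f[8])
        cigar = next(t[5:] for t in f[12:] if t.startswith("cg:Z:"))
        qpos = q.offsets[qname] + qs
        if strand == "+":
            tpos = q.offsets[tname] + ts
        else:
            tpos = q.n + q.offsets[tname] + (tlen - te)
        run: list[tuple[int, int]] = []

        def flush():
            nonlocal run
            if len(run) >= max(min_match_len, 1):
                pairs.extend((a, b) for a, b in run if a != b)
            run = []

        for m in _CIG.finditer(cigar):
            ln, op = int(m.group(1)), m.group(2)
            if op in "M=":
                for _ in range(ln):
                    if op == "=" or q.char(qpos) == q.char(tpos):
                        run.append((qpos, tpos))
                    else:
                        flush()
                    qpos += 1
                    tpos += 1
            else:
                flush()
                if op in "XIS":
                    qpos += ln
                if op in "XDN":
                    tpos += ln
        flush()
    return pairs


class PlainUnionFind:
    """Textbook union-find over arbitrary hashables."""

    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def closure_partition(fasta_text: str, paf_text: str, min_match_len: int = 0):
    """Forward-position partition from exhaustive character-level closure.

    Expands every matched character pair, adds the strand mirror edges
    implicitly by projecting both ends onto the forward strand, and returns
    frozenset components covering [0, n).
    """
    q = QSpace(parse_fasta_text(fasta_text))
    uf = PlainUnionFind()
    for p in range(q.n):
        uf.find(p)
    for a, b in expand_paf_char_pairs(paf_text, q, min_match_len):
        fa = a if a < q.n else q.mirror(a)
        fb = b if b < q.n else q.mirror(b)
        uf.union(fa, fb)
    groups: dict = {}
    for p in range(q.n):
        groups.setdefault(uf.find(p), []).append(p)
    return {frozenset(g) for g in groups.values()}
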