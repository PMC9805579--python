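"""Synthetic pangenome fixtures with exact ground-truth alignments.

A random ancestor sequence is mutated independently into a set of
haplotypes (SNPs and short indels at given per-base rates, plus a number
of inverted segments per haplotype).  Because every edit is recorded
against ancestor coordinates, exact base-level alignments can be written
for each haplotype against the ancestor and — by composing the two edit
scripts through the ancestor — for every ordered pair of haplotypes,
yielding a mutually consistent symmetric all-vs-all PAF without running an
aligner.

Inverted segments carry no internal point mutations; a haplotype's
inversion is emitted as a separate '−'-strand record against any partner
that maps the same ancestor interval forward and gap-free.  Pairwise
records for a pair whose inversions overlap are simply omitted (alignment
sets need not be complete).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqstore import revcomp

__all__ = [
    "MutationModel",
    "Haplotype",
    "TruthSet",
    "simulate_pangenome",
    "truth_to_paf",
    "permute_input",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class MutationModel:
    """Per-haplotype mutation parameters (all rates per ancestor base)."""

    snp_rate: float = 0.005
    indel_rate: float = 0.0005
    indel_length: float = 3.0  # geometric mean length
    inversion_count: int = 1
    inversion_length: tuple[int, int] = (100, 500)
    seed: int = 42

    def __post_init__(self):
        for name in ("snp_rate", "indel_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.indel_length < 1.0:
            raise ValueError("indel_length must be >= 1")
        if self.inversion_count < 0:
            raise ValueError("inversion_count must be >= 0")


@dataclass
class Haplotype:
    """One derived sequence plus its per-base mapping to the ancestor.

    ``hap_of_anc[p]`` is the haplotype position carrying ancestor position
    p (−1 if deleted); ``anc_orient[p]`` is '+' for a forward copy and '−'
    inside an inverted segment.  ``ins_after[p]`` is sequence inserted
    immediately after the copy of ancestor position p.
    """

    name: str
    seq: str
    hap_of_anc: list[int]
    anc_orient: list[str]
    ins_after: dict[int, str] = field(default_factory=dict)
    inversions: list[tuple[int, int]] = field(default_factory=list)  # anc [s, e)


@dataclass
class TruthSet:
    """Ancestor, haplotypes and the machinery to emit truth alignments."""

    ancestor: str
    haplotypes: list[Haplotype]

    def fasta_text(self, include_ancestor: bool = False) -> str:
        lines = []
        if include_ancestor:
            lines.append(">anc")
            lines.append(self.ancestor)
        for h in self.haplotypes:
            lines.append(f">{h.name}")
            lines.append(h.seq)
        return "\n".join(lines) + "\n"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(name: str, ancestor: str, model: MutationModel, rng: np.random.Generator) -> Haplotype:
    L = len(ancestor)
    # -- choose non-overlapping inverted segments -------------------------
    inversions: list[tuple[int, int]] = []
    lo, hi = model.inversion_length
    for _ in range(model.inversion_count):
        for _attempt in range(100):
            length = int(rng.integers(lo, hi + 1))
            if length >= L:
                continue
            s = int(rng.integers(0, L - length))
            e = s + length
            if all(e < s2 or s > e2 for s2, e2 in inversions):
                inversions.append((s, e))
                break
    inversions.sort()
    in_inversion = np.zeros(L, dtype=bool)
    for s, e in inversions:
        in_inversion[s:e] = True

    # -- SNPs --------------------------------------------------------------
    snp_mask = (rng.random(L) < model.snp_rate) & ~in_inversion
    snps: dict[int, str] = {}
    for p in np.flatnonzero(snp_mask):
        old = ancestor[p]
        choices = [b for b in _BASES if b != old]
        snps[int(p)] = choices[int(rng.integers(0, 3))]

    # -- indels ------------------------------------------------------------
    indel_mask = (rng.random(L) < model.indel_rate) & ~in_inversion & ~snp_mask
    deleted = np.zeros(L, dtype=bool)
    ins_after: dict[int, str] = {}
    for p in np.flatnonzero(indel_mask):
        p = int(p)
        if deleted[p]:
            continue
        length = int(rng.geometric(1.0 / model.indel_length))
        if rng.random() < 0.5:
            ins_after[p] = _random_seq(rng, length)
        else:
            # delete [p+1, p+1+length), clipped at inversions / sequence end
            q = p + 1
            while q < L and q < p + 1 + length and not in_inversion[q]:
                deleted[q] = True
                q += 1

    # -- build the haplotype and its maps ----------------------------------
    parts: list[str] = []
    hap_of_anc = [-1] * L
    anc_orient = ["+"] * L
    hap_len = 0
    inv_iter = iter(inversions)
    next_inv = next(inv_iter, None)
    p = 0
    while p < L:
        if next_inv is not None and p == next_inv[0]:
            s, e = next_inv
            segment = revcomp(ancestor[s:e])
            parts.append(segment)
            for u in range(e - s):
                hap_of_anc[e - 1 - u] = hap_len + u
                anc_orient[e - 1 - u] = "-"
            hap_len += e - s
            p = e
            next_inv = next(inv_iter, None)
            continue
        if not deleted[p]:
            parts.append(snps.get(p, ancestor[p]))
            hap_of_anc[p] = hap_len
            hap_len += 1
        if p in ins_after and not deleted[p]:
            ins = ins_after[p]
            parts.append(ins)
            hap_len += len(ins)
        p += 1
    seq = "".join(parts)
    if not seq:
        raise ValueError(f"mutation model produced an empty haplotype {name!r}")
    ins_after = {p: s for p, s in ins_after.items() if not deleted[p]}
    return Haplotype(name, seq, hap_of_anc, anc_orient, ins_after, inversions)


def simulate_pangenome(
    ancestor_length: int,
    n_haplotypes: int,
    model: MutationModel,
) -> TruthSet:
    """Simulate a small pangenome with recorded ground truth."""
    if ancestor_length < 100:
        raise ValueError("ancestor_length must be >= 100")
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2")
    rng = np.random.default_rng(model.seed)
    ancestor = _random_seq(rng, ancestor_length)
    haps = [
        _mutate(f"hap{i + 1}", ancestor, model, rng) for i in range(n_haplotypes)
    ]
    return TruthSet(ancestor=ancestor, haplotypes=haps)


# ---------------------------------------------------------------------------
# Truth → PAF
# ---------------------------------------------------------------------------


class _CigarBuilder:
    def __init__(self):
        self.ops: list[tuple[str, int]] = []

    def push(self, op: str, n: int = 1) -> None:
        if n <= 0:
            return
        if self.ops and self.ops[-1][0] == op:
            self.ops[-1] = (op, self.ops[-1][1] + n)
        else:
            self.ops.append((op, n))

    def text(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)

    def matched(self) -> int:
        return sum(n for op, n in self.ops if op == "=")

    def query_span(self) -> int:
        return sum(n for op, n in self.ops if op in "=XI")

    def target_span(self) -> int:
        return sum(n for op, n in self.ops if op in "=XD")

    def block(self) -> int:
        return sum(n for _op, n in self.ops)


def _paf_line(qname, qlen, qs, qe, strand, tname, tlen, ts, te, cig: _CigarBuilder) -> str:
    return "\t".join(
        str(x)
        for x in (
            qname, qlen, qs, qe, strand, tname, tlen, ts, te,
            cig.matched(), cig.block(), 60, f"cg:Z:{cig.text()}",
        )
    )


def _compare_run(query: str, target: str, strand: str) -> _CigarBuilder:
    """Per-base =/X CIGAR for two equal-length segments ('−': query vs
    reverse complement of target)."""
    cig = _CigarBuilder()
    t = target if strand == "+" else revcomp(target)
    for a, b in zip(query, t):
        cig.push("=" if a == b else "X")
    return cig


def _forward_windows(L: int, *hap_pair: Haplotype) -> list[tuple[int, int]]:
    """Maximal ancestor intervals avoiding every inversion of both haps."""
    blocked = sorted(
        seg for h in hap_pair for seg in h.inversions
    )
    windows = []
    pos = 0
    for s, e in blocked:
        if s > pos:
            windows.append((pos, s))
        pos = max(pos, e)
    if pos < L:
        windows.append((pos, L))
    return windows


def _collinear_record(
    q: Haplotype, t: Haplotype, ws: int, we: int, L: int
) -> str | None:
    """One pairwise record over an ancestor window where both map forward."""
    # trim to the first/last ancestor position both haplotypes retain
    ps = [p for p in range(ws, we) if q.hap_of_anc[p] >= 0 and t.hap_of_anc[p] >= 0]
    if not ps:
        return None
    p0, p1 = ps[0], ps[-1]
    cig = _CigarBuilder()
    for p in range(p0, p1 + 1):
        qi, ti = q.hap_of_anc[p], t.hap_of_anc[p]
        if qi >= 0 and ti >= 0:
            cig.push("=" if q.seq[qi] == t.seq[ti] else "X")
        elif qi >= 0:
            cig.push("I")
        elif ti >= 0:
            cig.push("D")
        if p < p1:
            if p in q.ins_after and q.hap_of_anc[p] >= 0:
                cig.push("I", len(q.ins_after[p]))
            if p in t.ins_after and t.hap_of_anc[p] >= 0:
                cig.push("D", len(t.ins_after[p]))
    qs, qe = q.hap_of_anc[p0], q.hap_of_anc[p1] + 1
    ts, te = t.hap_of_anc[p0], t.hap_of_anc[p1] + 1
    return _paf_line(
        q.name, len(q.seq), qs, qe, "+", t.name, len(t.seq), ts, te, cig
    )


def _maps_forward_gapfree(h: Haplotype, s: int, e: int) -> bool:
    """True if h copies ancestor [s, e) forward with no indels inside."""
    prev = None
    for p in range(s, e):
        i = h.hap_of_anc[p]
        if i < 0 or h.anc_orient[p] != "+":
            return False
        if prev is not None and i != prev + 1:
            return False
        if p in h.ins_after and p < e - 1:
            return False
        prev = i
    return True


def _inversion_records(q: Haplotype, t: Haplotype) -> list[str]:
    """'−'-strand records for inverted segments of either side of a pair."""
    out = []
    # query's inversions against a forward, gap-free target image
    for s, e in q.inversions:
        if _maps_forward_gapfree(t, s, e):
            qs = q.hap_of_anc[e - 1]  # inversion start in hap coordinates
            qe = q.hap_of_anc[s] + 1
            ts, te = t.hap_of_anc[s], t.hap_of_anc[e - 1] + 1
            cig = _compare_run(q.seq[qs:qe], t.seq[ts:te], "-")
            out.append(
                _paf_line(q.name, len(q.seq), qs, qe, "-", t.name, len(t.seq), ts, te, cig)
            )
    # target's inversions against a forward, gap-free query image
    for s, e in t.inversions:
        if _maps_forward_gapfree(q, s, e):
            qs, qe = q.hap_of_anc[s], q.hap_of_anc[e - 1] + 1
            ts = t.hap_of_anc[e - 1]
            te = t.hap_of_anc[s] + 1
            cig = _compare_run(q.seq[qs:qe], t.seq[ts:te], "-")
            out.append(
                _paf_line(q.name, len(q.seq), qs, qe, "-", t.name, len(t.seq), ts, te, cig)
            )
    return out


def _anc_haplotype(ancestor: str) -> Haplotype:
    L = len(ancestor)
    return Haplotype("anc", ancestor, list(range(L)), ["+"] * L)


def truth_to_paf(truth: TruthSet, mode: str = "all-vs-all") -> str:
    """Emit the truth alignment set as PAF text.

    ``all-vs-all``: every ordered haplotype pair, composed through the
    ancestor (both orientations of each pair appear, as in symmetric
    aligner output).  ``star``: each haplotype against the ancestor only.
    """
    L = len(truth.ancestor)
    lines: list[str] = []
    if mode == "star":
        anc = _anc_haplotype(truth.ancestor)
        for h in truth.haplotypes:
            for ws, we in _forward_windows(L, h):
                rec = _collinear_record(h, anc, ws, we, L)
                if rec:
                    lines.append(rec)
            lines.extend(_inversion_records(h, anc))
    elif mode == "all-vs-all":
        for q in truth.haplotypes:
            for t in truth.haplotypes:
                if q is t:
                    continue
                for ws, we in _forward_windows(L, q, t):
                    rec = _collinear_record(q, t, ws, we, L)
                    if rec:
                        lines.append(rec)
                lines.extend(_inversion_records(q, t))
    else:
        raise ValueError(f"unknown PAF mode {mode!r}")
    return "".join(line + "\n" for line in lines)


def permute_input(fasta_text: str, paf_text: str, seed: int) -> tuple[str, str]:
    """Reproducibly shuffle FASTA record order and PAF line order."""
    rng = np.random.default_rng(seed)
    records = []
    for chunk in fasta_text.split(">"):
        if chunk.strip():
            records.append(">" + chunk.rstrip("\n") + "\n")
    order = rng.permutation(len(records))
    fasta_out = "".join(records[i] for i in order)
    lines = [ln for ln in paf_text.splitlines() if ln]
    order = rng.permutation(len(lines))
    paf_out = "".join(lines[i] + "\n" for i in order)
    return fasta_out, paf_out
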