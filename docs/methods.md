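# Methods

## Model

`pafgraph` induces a bidirected variation graph G = (V, E, P) from a set
of sequences S and pairwise alignments between them. The coordinate
universe is Q = S ∨ S̄: positions [0, |S|) address the forward
concatenation of the inputs, positions [|S|, 2|S|) the per-sequence
mirrored reverse complements. The reverse half is never materialized;
`char_at` complements the mirrored forward character on demand, and the
mirror map is a per-sequence involution that never crosses sequence
boundaries. All coordinates are 0-based half-open (PAF's native
convention, so no conversion is ever applied).

Alignments are reduced to *range matches*: each maximal run of CIGAR
match operations becomes a pair of equal-length Q ranges read in parallel
(`a_start+t ↔ b_start+t`). The target range of a '−'-strand record lives
in the reverse half of Q, so an inversion is simply a forward/reverse
range pair; no separate strand bookkeeping is needed downstream. CIGAR
'=' is trusted; 'M' is verified base-by-base and split at unequal pairs
exactly like 'X', because a match must assert character identity — an
unverified mismatch under 'M' would incorrectly merge distinct
characters. An '=' over unequal bases is reported as corrupt input the
moment its closure is assembled.

The symmetric, deduplicated match array, sorted by first-range start with
a prefix maximum over first-range ends, serves as an implicit interval
tree: a point query binary-searches to the insertion position and walks
left only while the prefix maximum still allows an overlap, giving
O(log n + occ) behaviour without tree pointers.

Induction scans forward Q positions in ascending order. Each unseen
position seeds a transitive closure — the connected component of the
character-level match graph, including strand mirrors — which contributes
one character to the graph sequence V and one (position, orientation)
mapping per member. Consecutive mappings compress into ranges, yielding
Z : Q → V and its inverse Z̄. Two mechanisms implement the closure and
must agree bit for bit (a test asserts this):

* a union-find over forward positions augmented with an orientation
  parity bit (path compression + union by size), fed by expanding each
  canonical range match once — the default;
* a per-position breadth-first search that queries the interval tree for
  the partners of one character at a time, marking used characters in a
  seen-bitvector.

Orientation parity makes inverted homology exact: a member with parity 1
reads the complement of the closure character. A parity contradiction
(a character forced to equal its own complement) or a base disagreement
inside a closure is a hard error naming the positions involved, since
either can only arise from an alignment asserting identity over unequal
bases.

## Compaction, paths, edges

Node boundaries are marked in a bitvector B over V at position 0 and at
the V image of every Z range start and one-past-end; node ids are 1-based
ranks. After the final global re-merge of Z ranges into maximal runs, the
set of Z̄ ranges overlapping V position i changes exactly at those range
endpoints, so this endpoint rule is equivalent to detecting overlap-set
changes — and every remaining range break at a node boundary is a genuine
branch point (a path starts, ends, jumps, or flips orientation there), so
no further merge of linear components is needed: an additional
identically-traversed merge pass would be a no-op.

Paths walk each sequence's Z ranges in Q order, splitting each range's V
image at node boundaries; reverse-mapped ranges emit '−' steps in
reversed segment order, so each path spells its input exactly (node
sequences reverse-complemented on '−' steps). Edges are the unique
consecutive step pairs over all paths, canonicalized so an edge and its
reverse-complement image are one record (the lexicographically smaller
form under (id, orientation) is stored). GFA v1.0 output is
byte-deterministic: H, S ascending by id, L in canonical sort order, P in
input-sequence order, with `0M` link overlaps and `*` path overlaps.

## Parameters

* `min_match_len` (`-k`, default 0): drop maximal exact-match runs
  shorter than k bases, measured per run after splitting at mismatches
  and indels. Larger k grows the graph monotonically; past the longest
  run the graph degenerates to one private node per sequence.
* `partition_size` (default 1,000,000 bases): bounds the span of scan
  positions whose mappings are held uncompressed at once. Ranges are
  flushed per partition and re-merged in a final pass, so the setting
  cannot change V, Z, or the emitted GFA (tested byte-for-byte). The
  default suits desk-scale inputs of a few megabases.
* `--threads` is accepted for interface compatibility; execution is
  serial and output is identical for any value.

## Synthetic pangenomes

The fixture generator derives n haplotypes from a random ancestor:
SNPs (default 0.005/bp, substituting a uniformly chosen different base),
indels (default 0.0005/bp, geometric length with mean 3, insertion or
deletion with equal probability), and a fixed number of inverted segments
per haplotype (default 1, length uniform in [100, 500] bp — large enough
to exceed typical k filters, small relative to the 10 kb default ancestor).
The default rates give roughly 1% pairwise divergence, i.e. exact-match
runs of ~100 bp, comparable to within-species assembly comparisons.

Every edit is recorded against ancestor coordinates, so alignments are
emitted exactly rather than estimated: per-haplotype records against the
ancestor (star mode), or pairwise records composed through the ancestor
(all-vs-all mode, both orientations of every pair, as symmetric aligner
output would contain). Composition sidesteps aligner nondeterminism,
which would otherwise confound order-invariance experiments. Inverted
segments become separate '−'-strand records against any partner that maps
the same ancestor interval forward and gap-free; pairs whose inversions
overlap simply omit those records, which is valid since an alignment set
need not be complete.

What the generator does **not** emulate: realistic mutation spectra,
recombination, tandem repeats and other self-homology, structural
variation beyond inversions, sequencing error, or the soft-clipped /
partial mappings real aligners produce. Passing tests therefore
demonstrate correctness of the induction contracts (losslessness,
transitivity, order and partition invariance, match embedding) on clean,
mutually consistent alignment sets — not robustness to the noisier,
sometimes self-contradictory output of real aligners, where conflicting
records would surface as closure-conflict errors rather than silently
merged characters.

## Numerical and design choices

* Scan order is forward Q ascending; reverse-half positions are never
  seeded. A closure's character is read on the strand of its
  first-scanned member, which fixes node numbering and strand choice
  deterministically; permuting input sequence order can therefore only
  renumber or flip nodes, leaving length/node/edge counts unchanged.
* Sorting tie-break for matches is (a_start, b_start, length); ties in
  edge canonicalization resolve by (id, orientation). Both exist purely
  to make output byte-deterministic.
* Self-identity matches (a range aligned to itself in place) are dropped
  at parse time; they carry no information.
* Duplicate alignment records (A→B and B→A in symmetric PAF) collapse at
  the range-match level after canonicalization.
* Two aligned N characters merge like any other equal pair, preserving
  losslessness; IUPAC ambiguity codes other than N are rejected at load
  time rather than guessed at.
* Empty match sets, single-record inputs and k = 0 are all valid; the
  degenerate graph is one node per input sequence.

## Acceptance experiment scale

`scripts/acceptance.py` runs the order-invariance experiment on five
10 kb haplotypes and 20 permutations — a problem size chosen so the full
experiment recomputes in seconds while still exercising SNPs, indels and
inversions across a non-trivial alignment set. The expected standard
deviation of graph length and node count across permutations is exactly 0.

## Known limitations

* In-memory only; inputs beyond tens of megabases are out of scope.
* Circular sequences are treated as linear; no W lines, GFA v1.0 only.
* The graph is exactly as good as its alignment set: under-alignment
  (high k, sparse PAF) yields redundant private nodes, and uncoordinated
  all-vs-all alignments of repeats can produce densely looping regions.
  No downstream normalization is applied.
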