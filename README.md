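# pafgraph

Lossless pangenome variation graph induction from sequences and their
pairwise alignments.

## The problem

A collection of genomes aligned all-vs-all implies a *variation graph*
G = (V, E, P): nodes V carry DNA sequence, edges E connect node strands,
and paths P embed each input genome as a walk that spells it exactly.
Progressive graph builders depend on a reference or on input order;
`pafgraph` instead induces the graph symmetrically from the alignment set
alone, so the shape of the graph (total length, node and edge counts) is
independent of the order in which genomes are given.

The construction works over Q = S ∨ S̄, the concatenation of all input
sequences and their (implicit) reverse complements. Each alignment match
m = (i, j) asserts that two characters of Q are identical. The transitive
closure m⁺ of a match — all positions linked through chains of matches and
strand mirrors — collapses to a single graph character c(m⁺). Scanning Q
in order and closing each unseen character yields the graph sequence V and
a bidirectional range mapping Z : Q → V (with inverse Z̄) from which paths,
node boundaries and edges all follow. Matches are held run-length
compressed as pairs of ranges in a sorted array queried as an implicit
interval tree; runs of V traversed identically by every path are compacted
into single nodes via a boundary bitvector with rank support.

Because every input character maps to exactly one graph position, the
result is lossless: each path spells its input sequence character for
character, and every input match is embedded as a shared node. A minimum
exact-match length filter (`-k`) optionally drops short match runs,
trading a larger graph for simpler local topology.

## Worked example

Simulate a small pangenome (three haplotypes derived from a 3 kb ancestor,
with SNPs, indels and one inversion each, plus the exact all-vs-all PAF
implied by the mutations), induce its graph, and inspect it:

```
$ pafgraph simulate --length 3000 -n 3 --seed 11 -o demo
wrote demo.fa and demo.paf
$ pafgraph induce -s demo.fa -p demo.paf -g demo.gfa
graph length: 3767 bp	nodes: 127	edges: 174	components: 1
$ pafgraph stats demo.gfa
length	3767
nodes	127
edges	174
paths	3
components	1
```

The graph carries 3767 bp of sequence for 9 kb of input: shared sequence
collapses onto common nodes while variant sites form bubbles; the three
P lines spell the three haplotypes exactly. Filtering short matches grows
the graph, since dropped matches leave sequence private:

```
$ pafgraph induce -s demo.fa -p demo.paf -g demo.k29.gfa -k 29
graph length: 3910 bp	nodes: 107	edges: 145	components: 1
```

`pafgraph permute` reshuffles sequence and alignment record order for
order-bias experiments. The same functionality is available as a library:

```python
import pafgraph
graph = pafgraph.induce_graph("demo.fa", "demo.paf", min_match_len=0)
graph.path_sequence("hap1")   # spells the input haplotype exactly
```

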