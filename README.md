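# asmcomplexity

How hard is a genome to assemble from short reads — not because of noise or
coverage, but because of its own repeat structure?

`asmcomplexity` answers that question for the idealized case: given every
length-*k* substring of a genome together with its exact multiplicity, it
measures what any assembler could possibly recover.  It is aimed at people
evaluating assemblers or read-length trade-offs, and at anyone studying the
repeat structure of (mostly prokaryotic, mostly circular) genomes.

The package:

- builds the **de Bruijn multigraph** D_k(g): one node per (k−1)-mer, one
  edge per k-mer occurrence, parallel edges and self-loops included;
- applies **information-preserving simplifications** (path compression,
  tree-like-region collapse, half-decision splitting, optional pigeonhole
  multiplicity inference, non-decision-node-to-edge conversion) that shrink
  the graph without changing the set of consistent reconstructions;
- **counts reconstructions exactly**.  With t a fixed final node,
  a_uv the edge multiplicities, r_u = d⁺(u) (+1 if u = t), and L the matrix
  with r_u − a_uu on the diagonal and −a_uv elsewhere,

      W(G, t) = det(L with row/column t deleted) · ∏_u (r_u − 1)! / ∏_{u,v} a_uv!

  is the number of distinct words spellable from G ending at t — an
  adaptation of the BEST theorem that corrects for interchangeable parallel
  edges and allows trails as well as circuits.  For a non-periodic circular
  genome, W(G, t)/d⁺(t) counts cyclically distinct reconstructions;
- extracts **idealized contigs** (one per edge instance of the simplified
  graph; their lengths sum exactly to the genome length) and the **N50 /
  relative N50** they achieve — an upper bound for real assemblers;
- classifies annotated **genes as reconstructible** or not: a gene survives
  if its coding interval fits inside the unambiguous region walked forward
  from its start before a backward-then-forward decision pair is crossed.

Everything is validated against an exhaustive-enumeration oracle on small
instances, and a seeded synthetic-genome generator with planted repeat
families makes the whole test suite self-contained.

## A worked example

The string `sababababab` at k = 5 (from `examples/worked_example.py`):

```
nodes:  ['abab', 'baba', 'saba']
  edge abab -> baba  x3
  edge baba -> abab  x3
  edge saba -> abab  x1
trail endpoints: s=saba, t=abab

Eulerian trails (BEST formula):      36
Eulerian trails (exhaustive search): 36
distinct consistent words:           1
the one word: 'sababababab'
```

There are 3!·3! = 36 Eulerian trails — the parallel copies of each repeat
edge can be traversed in any order — yet all of them spell the same string.
Tour counts exaggerate ambiguity; the word count W(G, t) = 1 says this
"genome" is perfectly assemblable from 5-mers.

The other scripts in `examples/` each demonstrate one capability with a
small synthetic genome: graph simplification (`simulate_and_simplify.py`),
reconstruction counting across read lengths (`count_reconstructions.py`),
contigs and N50 (`contigs_and_n50.py`), and per-gene classification
(`gene_reconstructibility.py`).

## Command line

A thin CLI mirrors the library:

```bash
asmcomplexity simulate --length 800 --seed 42 --repeat 50,3 --out-prefix sim
asmcomplexity build sim.fasta -k 25 --out sim.gfa
asmcomplexity simplify sim.fasta -k 25 --out sim.min.gfa --stats stats.tsv
asmcomplexity count sim.fasta -k 25
asmcomplexity contigs sim.fasta -k 25 --out contigs.fasta --tsv n50.tsv
asmcomplexity genes sim.fasta sim.ptt -k 25 --out genes.tsv --summary sum.tsv
asmcomplexity report sim.fasta --k-list 15,25,35,50
```

Graphs are serialized as GFA 1.0 (multiplicities in an `RC:i` tag,
conversion labels in `LB:Z`); annotations are read from GenBank `.ptt`
tables or minimal GFF3.

## Scope

Forward-strand, error-free, full-coverage reads with known multiplicities:
this is deliberately an upper-bound model.  No reverse-complement
canonicalization, no coverage or sequencing-error simulation, no paired-end
modeling (a long read is a conservative stand-in for a read pair of the
same span).  See `docs/methods.md` for the model, the parameter choices,
and known limitations.
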