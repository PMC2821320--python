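# Methods

## The model

A genome is a string g over a declared alphabet (default ACGT), with
explicit circular or linear topology.  The read model is idealized: all
length-k substrings of the forward strand are known, each with its exact
multiplicity.  Circular genomes contribute one k-mer per position (wrapping
the origin), so the de Bruijn multigraph D_k(g) — a node per (k−1)-mer, an
edge per k-mer occurrence — is Eulerian-balanced; linear genomes contribute
|g|−k+1 k-mers and have at most one imbalanced pair (s, t), the endpoints
of every Eulerian trail.  Every reconstruction consistent with the read
information is the spelling of an Eulerian trail/circuit, and vice versa.

This is an upper-bound model by design: no sequencing errors, no missing
k-mers, no reverse complements, multiplicities given rather than estimated
from coverage.  Anything unreachable here is unreachable for a real
assembler; much that is reachable here will not be in practice.

## Spelling

Walking an edge appends the successor's sequence minus the k−2 symbols it
shares with its predecessor.  Node sequences grow under simplification, but
the k−2 overlap along every edge is an invariant, so the rule never
changes.  One boundary case matters: the final node of a circuit
contributes only its first k−1 symbols (the walk stops once the last
edge's k-mer is consumed), while the final node of a trail is spelled in
full.  On the unsimplified graph both readings coincide; on compressed
graphs only this one conserves length (|g|+k−1 for a circular spelling,
|g| for a linear one) and keeps the word set invariant under merging.
Because simplification can re-anchor which rotations of a circular genome
are spellable as linear words, word-set comparisons for circular genomes
are made on canonical cyclic words (strip the final k−1 symbols, minimal
rotation).

## Simplification

All transformations preserve the set of consistent reconstructions; the
test suite asserts this literally, via exhaustive enumeration, on every
instance small enough to enumerate.

- **Path compression** merges (u, v) when v is u's only successor and u is
  v's only predecessor — valid across parallel edges, which the merge
  consumes; v→u edges become self-loops.
- **Tree-like-region collapse** works leaf-by-leaf rather than via an
  explicit cycle graph.  Two leaf shapes exist: a pendant 2-cycle (u the
  sole neighbour of v, u carrying exactly one external in- and out-edge
  instance and no self-loop) and a self-loop rosette (one external in/out
  instance).  Each has a unique local Eulerian sub-tour whose spelling
  replaces the region; path compression re-runs after every collapse.  The
  single-instance requirement is essential: with two external visits the
  interleaving of the pendant cycles is genuinely ambiguous.
- **Half-decision splitting** applies to nodes with one distinct
  predecessor and several distinct successors (or the mirror): the node is
  split into per-successor copies, shifting the decision toward the unique
  neighbour.  Distinct-neighbour counting is the operative criterion — in a
  balanced graph in- and out-degrees are always equal, so degrees cannot
  identify half decisions.  Splitting cascades exhaustively within each
  direction; backward decisions are processed before forward ones, then
  paths recompress.
- **Pigeonhole inference** (off by default): when the heaviest in-edge
  u→v (c_u) and heaviest out-edge v→w (c_w) satisfy c_u > d⁺(v) − c_w,
  at least f = c_u + c_w − d⁺(v) traversals must pair u with w; those f
  are rerouted through a dedicated copy of v.  Nodes with a single distinct
  predecessor and successor are skipped, which also guarantees
  termination.  It ships disabled because it tends to interact badly with
  the other rewrites and enlarge final graphs.
- **Non-decision-to-edge conversion** replaces each remaining
  one-in/one-out node v by an edge u→w labeled with v's sequence.  After
  the full pipeline a multi-node graph contains only nodes with more than
  one predecessor and more than one successor.

The pipeline order is fixed: compression; tree collapse (with interleaved
compression); backward then forward splitting plus the newly enabled
compressions; conversion.  `ReductionStats` records edge-instance counts
after each stage; per-stage percentages are relative to the previous stage,
the total relative to the post-compression baseline.

Two deliberate boundary rules:

- **Trail endpoints.**  On linear-genome graphs, any rewrite whose
  soundness needs "every visit to u exits" or "every visit to v is an
  entry" is skipped at t and s respectively, and a merge fusing s and t
  into one node is refused — it would close the trail into a circuit and
  add rotated words.
- **Terminal rosette.**  A fully resolved circular genome ends as a single
  node with one self-loop (net length exactly |g|), not an edgeless node:
  the self-loop leaf rule requires an external in/out, so a whole-graph
  rosette is left intact.  This keeps contig-length conservation exact.

## Counting

W(G, t) = det(minor of L at t) · ∏(r_u − 1)! / ∏ a_uv! counts distinct
words ending at t; the determinant is the arborescence count of the
matrix-tree theorem, the factorials are the BEST theorem's degree terms
extended by +1 at t (trails), and the division removes permutations of
interchangeable parallel edges.  On graphs whose parallel groups carry
distinct labels the division is per (u, v, label) group, since differently
labeled edges spell different words.  Raw Eulerian trail counts (parallel
instances distinguishable) come from the same arborescence machinery:
trail graphs are closed with one t→s edge; circuit counts are linearized
at a fixed start node.

For circular genomes, W(G, t)/d⁺(t) counts cyclically distinct
reconstructions, independent of t.  Divisibility by d⁺(t) is asserted, not
rounded — a failure indicates periodicity or a bug.  A graph is *periodic*
when some circuit's node sequence has a nontrivial cyclic period; then the
division undercounts rotational collapse and `count_circular` refuses.
Detection: any node visited exactly once pins the rotation ("no");
otherwise graphs with ≤14 edge instances are checked exhaustively;
otherwise "possibly" is reported and counting refuses unless overridden.

Exact arithmetic uses arbitrary-precision integers with sympy's
fraction-free (Bareiss) determinant, refused above 2000 nodes (counts in
real genomes reach the 2^900 scale); log2 mode evaluates the same
expression with floating LU and log-gamma.  `reduce_for_counting` (path
compression + tree collapse) shrinks the matrix to the surviving decision
nodes without changing W for trail graphs or W/d⁺(t) for circuit graphs;
half-decision splitting is deliberately excluded there because it
duplicates node sequences, after which distinct node orderings can spell
identical words and the determinant would overcount.

## Contigs and N50

One contig per edge *instance* of the maximally simplified graph: an
unlabeled edge u→v contributes seq(u) with length len(u) − (k−2); a labeled
edge contributes seq(u) plus its label with length
len(u) + len(label) − 2(k−2), the subtractions discounting the k−2 symbols
shared with the neighbouring contigs.  Counting per instance (an edge of
multiplicity m yields m identical contigs) is what makes
Σ lengths = |g| exact for circular genomes — each decision node appears in
the genome exactly as often as it has outgoing edge instances.  For linear
genomes the identity is off by k−1 by construction and is reported with
that caveat rather than adjusted.  N50 is the largest m such that contigs
of length ≥ m cover at least half the genome, evaluated over the realized
length multiset; relative N50 divides by |g|.

## Gene reconstructibility

Genes are tested on a graph with trees collapsed and paths compressed —
no splitting, no conversion — with node occurrence positions located in
the genome.  The genome's own traversal is precomputed as a cyclic
decomposition into (node, occurrence) steps whose net intervals partition
the genome; a rare prefix ambiguity (one node's sequence a prefix of
another's at the same position) is resolved by backtracking to the unique
decomposition that closes the cycle.

The walk for a gene starts at the decomposition element owning the base of
its coding start (position `start` for + genes, `end` for − genes; a base
inside a k−2 overlap belongs to the downstream element).  Entering any
node with in-degree > 1 marks the walk as having passed a backward
decision; the first node with out-degree > 1 after that terminates it,
with that node's own region still covered.  The gene is reconstructible
iff its full forward-strand interval lies inside the covered region.  The
walk follows the true genomic path only — it is the path tracing the
gene's interval, so branch enumeration cannot change the verdict.  If the
start node itself has in-degree > 1 the walk begins polluted; forward
decisions alone never terminate anything.

Reverse-strand genes are evaluated on their forward-strand interval walked
5'→3' in genome coordinates from the node containing the coding start.
For a − gene whose body extends upstream beyond that node's region the
test is conservative (the walk cannot extend upstream), a known asymmetry
of this forward-only definition; stop-to-start backward walking is
deliberately not attempted.

Summaries report the percentage of reconstructible genes and, over
non-reconstructible genes whose description does not contain
"hypothetical", case-insensitive substring tallies of the keywords
("transpos", "insertion sequence", "integrase", "phage") associated with
mobile genetic elements.  Enrichment P-values are out of scope; the raw
tallies are emitted for downstream use.

## Synthetic genomes

`generate_genome` builds circular genomes as alternating unique spacers
and planted repeat copies: per family a random repeat sequence, its copies
interspersed between random background chunks (or laid adjacently for
tandem families), chunk sizes drawn from a multinomial over the remaining
length with a minimum spacer.  Candidates are rejected until every planted
sequence occurs exactly its requested number of times and every duplicated
`uniqueness_k`-mer (default 12 — comfortably above chance collisions at
the few-kb scale while leaving test k values of 13+ meaningful) is
attributable to a planted interval.  Generation is deterministic given the
seed; a manifest records every copy's position.

What this emulates: exact interspersed/tandem repeat families in an
otherwise repeat-free background.  What it does not: reverse-complement
repeats, diverged copies, skewed composition, plasmids, coverage or error
structure.  Tests passing on these genomes therefore certify the
combinatorics of repeat resolution, not robustness to real-data noise.

The enumeration oracle backtracks over all Eulerian trails/circuits
(parallel instances distinguishable, trail count = node-sequence count ×
∏ group factorials), spells each, and is capped at 14 edge instances: it
is exponential by design, existing to validate the polynomial-time
counting and the simplifications, never for production use.

## Problem sizes and numerical choices

The shipped tests run on genomes of 8–700 bp (oracle-checked instances at
≤14 edge instances, ~100 seeds; pipeline properties at 400–700 bp over
k ∈ {15, 25, 35, 50}; exact counting up to a few hundred nodes), sizes at
which every oracle cross-check is exhaustive and the whole suite runs in
seconds.  Determinants are exact integer (no tolerances); the only
floating comparison is log2-vs-exact agreement at 1e−9 relative.
Deterministic orderings everywhere: nodes are processed in id order, ids
are lexicographic ranks at construction and fresh integers thereafter, so
outputs are reproducible bit-for-bit for a given seed.

## Known limitations

- Forward strand only; no reverse-complement edge identification.
- Periodic circular genomes are detected and refused, not counted.
- `count_words` on graphs containing duplicated node sequences (e.g. after
  half-decision splitting) counts node orderings, which may exceed
  distinct words; use unsplit graphs (or `reduce_for_counting`) for word
  counts.
- Gene classification for reverse-strand genes is conservative, as above.
- The exact-mode node limit (2000) and oracle cap (14 edge instances) are
  configurable but deliberate.
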