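"""The classic three-node example: many tours, one genome.

The string "sababababab" read with k = 5 produces a de Bruijn graph with
three nodes and parallel edges.  There are 3!·3! = 36 distinct Eulerian
trails through it, because the three parallel copies of each repeat edge can
be traversed in any order — yet every one of them spells the same string.
Counting tours therefore overstates ambiguity; counting words is what
matters, and the determinant formula gets it exactly right.
"""

from asmcomplexity import (Genome, build_graph, classify_node,
                           count_eulerian_trails, count_words, enumerate_words)

genome = Genome("toy", "sababababab", "linear", alphabet=None)
graph = build_graph(genome, k=5)

print(f"genome: {genome.sequence!r} (linear, k=5)")
print(f"nodes:  {[graph.seq(u) for u in sorted(graph.nodes)]}")
for u, v, _label, mult in graph.edge_groups():
    print(f"  edge {graph.seq(u)} -> {graph.seq(v)}  x{mult}")
s, t = graph.terminals
print(f"trail endpoints: s={graph.seq(s)}, t={graph.seq(t)}")
for u in sorted(graph.nodes):
    print(f"  {graph.seq(u)}: {classify_node(graph, u)}")

trails = count_eulerian_trails(graph)
words = count_words(graph)
oracle = enumerate_words(graph)
print(f"\nEulerian trails (BEST formula):      {trails}")
print(f"Eulerian trails (exhaustive search): {oracle.trails}")
print(f"distinct consistent words:           {words.exact_count}")
print(f"the one word: {next(iter(oracle.distinct_words))!r}")
print("\n36 tours but a single word: parallel edges inflate tour counts, "
      "so assembly ambiguity must be measured in words.")
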