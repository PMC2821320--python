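"""How many genomes are consistent with perfect length-k reads?

For a fixed circular genome, the number of cyclically distinct
reconstructions W(G,t)/d+(t) is computed for increasing read lengths.  The
count can only fall as k grows (longer reads carry strictly more
information), reaching 1 when every repeat is spanned.  A genome made of a
single tandem repeat is periodic and the cyclic correction refuses it.
"""

from asmcomplexity import (Genome, build_graph, count_circular,
                           detect_periodicity, reduce_for_counting,
                           random_genome, PeriodicGraphError)

genome = random_genome(60, seed=11)
print(f"random circular genome, {len(genome)} bp")
for k in (4, 6, 8, 10):
    graph = reduce_for_counting(build_graph(genome, k))
    res = count_circular(graph)
    print(f"  k={k:2d}: {res.exact_count} consistent cyclic reconstruction(s) "
          f"(log2 = {res.log2_count:.2f})")
print("counts are non-increasing in k; 1 means the genome is fully "
      "determined by its k-mers.")

periodic = Genome("per", "ATATAT", "circular")
graph = build_graph(periodic, 3)
print(f"\n'ATATAT' at k=3: periodicity = {detect_periodicity(graph)}")
try:
    count_circular(graph)
except PeriodicGraphError as exc:
    print(f"cyclic counting refused: {exc}")
    print("periodic graphs need special treatment because rotations of one "
          "tour collapse onto fewer distinct cyclic words.")
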