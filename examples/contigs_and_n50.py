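"""Idealized contigs: the best any assembler could do with perfect reads.

Each edge of the maximally simplified graph is one unambiguous stretch of
the chromosome.  Their lengths sum exactly to the genome length, and the
N50 of this set is an upper bound on what a real assembler can achieve at
that read length.  Watch the relative N50 jump to 100% once k exceeds the
longest repeat.
"""

from asmcomplexity import (SimSpec, RepeatFamily, generate_genome,
                           build_graph, maximal_compress, extract_contigs, n50)

genome, _, _ = generate_genome(SimSpec(
    genome_length=700, seed=3,
    repeat_families=(RepeatFamily(30, 3), RepeatFamily(40, 2))))
print(f"synthetic circular genome, {len(genome)} bp, repeats of 30 (x3) and 40 (x2)")

for k in (15, 25, 35, 50):
    simplified, _ = maximal_compress(build_graph(genome, k))
    contigs = extract_contigs(simplified, with_sequence=False)
    report = n50([c.length for c in contigs], len(genome))
    total = sum(c.length for c in contigs)
    print(f"  k={k:2d}: {report.contig_count:2d} contigs, total {total} bp "
          f"(= genome length), N50 = {report.n50} "
          f"({report.relative_n50:.1f}% of the genome)")
print("relative N50 is non-decreasing in k; at k=50 both repeats are "
      "spanned and one contig covers everything.")
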