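"""Most genes survive short reads even when the genome does not.

A 3-copy repeat makes the whole genome ambiguous, but only the gene that
actually contains a repeat copy is affected: walking forward from each
gene's start, a gene fails only if the walk crosses a backward decision and
then a forward decision before the gene ends.  Here the repeat-bearing
"transposase" is the only casualty.
"""

import numpy as np

from asmcomplexity import Genome, GeneAnnotation, analyze_genes

rng = np.random.default_rng(7)
def rand(n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

R = rand(40)                      # the repeat, 3 copies
UA = "A" + rand(118) + "T"        # unique segments with pinned boundary bases
UB = "C" + rand(128) + "A"
UC = "G" + rand(108) + "C"
genome = Genome("demo", UA + R + UB + R + UC + R, "circular")

genes = [
    GeneAnnotation("transposase", len(UA) - 29, len(UA) + len(R) + 30, "+",
                   "IS-family transposase"),        # contains a full repeat copy
    GeneAnnotation("polA", len(UA) + len(R) + 21, len(UA) + len(R) + 90, "+",
                   "DNA polymerase"),               # unique region after the repeat
    GeneAnnotation("ligA", len(UA) + len(R) + len(UB) + len(R) + 11,
                   len(UA) + len(R) + len(UB) + len(R) + 80, "-",
                   "DNA ligase"),                   # unique region, reverse strand
]

report, graph = analyze_genes(genome, genes, k=21)
print(f"genome: {len(genome)} bp with a 3-copy 40-mer repeat; k = 21")
print(f"simplified gene-test graph: {len(graph.nodes)} nodes\n")
for gid, rec in report.per_gene.items():
    mark = "yes" if rec["reconstructible"] else "NO "
    print(f"  {gid:12s} reconstructible: {mark}  ({rec['reason']})")
print(f"\nfraction reconstructible: {report.fraction_reconstructible:.1f}%")
print(f"keyword tallies among failed, non-hypothetical genes: "
      f"{ {k: v for k, v in report.keyword_tallies.items() if v} }")
print("\nonly the repeat-carrying gene is lost - mobile elements, not genome "
      "size, are what short reads cannot resolve.")
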