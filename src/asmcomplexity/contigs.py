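"""Idealized contigs from a simplified graph, and the N50 statistic.

Every edge instance of the maximally compressed graph yields one contig:
the sequence of its source node, plus the edge's label when the edge was
created by non-decision-node conversion.  Lengths discount the k-2 symbols
shared with the next contig, so that the contig lengths of a circular genome
sum exactly to the genome length; an edge of multiplicity m yields m
identical contigs, which is what makes that conservation identity exact.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import KmerGraph, merge_seqs

__all__ = ["Contig", "N50Report", "extract_contigs", "n50"]


@dataclass(frozen=True)
class Contig:
    u: int
    v: int
    label: str | None
    instance: int
    length: int
    sequence: str | None = None

    @property
    def name(self) -> str:
        return f"{self.u}-{self.v}.{self.instance}"


@dataclass(frozen=True)
class N50Report:
    n50: int
    relative_n50: float  # percent of genome length
    contig_count: int
    genome_length: int


def extract_contigs(graph: KmerGraph, with_sequence: bool = True) -> list[Contig]:
    """One contig per edge INSTANCE of a simplified graph.

    An unlabeled edge u->v contributes seq(u) with length len(u) - (k-2); a
    labeled edge contributes seq(u) merged with its label, with length
    len(u) + len(label) - 2(k-2).  A fully resolved graph that is a single
    node without edges (a completely merged linear genome) yields one contig
    spelling the whole node.
    """
    k = graph.k
    o = k - 2
    if graph.total_edges() == 0:
        if len(graph.nodes) != 1:
            raise ValueError("edgeless graph with multiple nodes has no contigs")
        (u,) = graph.nodes
        seq = graph.seq(u)
        return [Contig(u, u, None, 0, len(seq), seq if with_sequence else None)]
    contigs = []
    for u, v, label, mult in graph.edge_groups():
        if label is None:
            seq = graph.seq(u)
            length = len(seq) - o
        else:
            seq = merge_seqs(graph.seq(u), label, k)
            length = len(graph.seq(u)) + len(label) - 2 * o
        if length < 1:
            raise ValueError(f"contig for edge {u}->{v} has length {length} < 1")
        for i in range(mult):
            contigs.append(Contig(u, v, label, i, length, seq if with_sequence else None))
    return contigs


def n50(contig_lengths: list[int], genome_length: int) -> N50Report:
    """Largest m such that contigs of length >= m cover >= half the genome."""
    if not contig_lengths:
        raise ValueError("empty contig list")
    if any(x <= 0 for x in contig_lengths):
        raise ValueError("contig lengths must be positive")
    if genome_length < max(contig_lengths):
        raise ValueError("genome shorter than its largest contig")
    half = genome_length / 2
    cum = 0
    for length in sorted(contig_lengths, reverse=True):
        cum += length
        if cum >= half:
            return N50Report(length, 100.0 * length / genome_length,
                             len(contig_lengths), genome_length)
    raise ValueError("contigs cover less than half the genome")
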