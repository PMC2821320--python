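"""Per-gene reconstructibility from idealized length-k reads.

A gene is reconstructible when its whole coding interval lies inside the
unambiguous region reachable by walking forward from the node containing its
coding start, before the walk crosses first a backward decision (a node with
more than one in-edge) and then a forward decision (more than one out-edge);
a full decision counts as both at once.  Forward decisions alone do not
confuse the walk — every edge must be used, so all branches can be followed —
but once a backward decision has "polluted" the walk, the next forward
decision makes the continuation locally undecidable.

Classification runs on a graph with tree-like regions collapsed and paths
compressed (no half-decision splitting, no node-to-edge conversion), and the
walk follows the genome's own node-occurrence decomposition, i.e. the path
that traces the gene's true interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import Genome, GeneAnnotation
from .graph import KmerGraph, build_graph, locate_occurrences
from .simplify import path_compress_inplace, collapse_trees_inplace

__all__ = [
    "WalkOutcome",
    "GeneReconReport",
    "DEFAULT_KEYWORDS",
    "prepare_recon_graph",
    "genome_decomposition",
    "locate_start_node",
    "is_reconstructible",
    "summarize_reconstructibility",
    "analyze_genes",
]

DEFAULT_KEYWORDS = ("transpos", "insertion sequence", "integrase", "phage")


@dataclass
class WalkOutcome:
    start_node: int
    explored_paths: list[list[int]] = field(default_factory=list)
    passed_backward: list[bool] = field(default_factory=list)
    terminated_at_forward: list[bool] = field(default_factory=list)
    #: (start, length) genome interval covered by each path
    covered_intervals: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GeneReconReport:
    per_gene: dict[str, dict]
    fraction_reconstructible: float | None  # percent; None for no genes
    keyword_tallies: dict[str, int]

    @property
    def n_genes(self) -> int:
        return len(self.per_gene)

    @property
    def n_reconstructible(self) -> int:
        return sum(1 for v in self.per_gene.values() if v["reconstructible"])


def prepare_recon_graph(genome: Genome, k: int) -> KmerGraph:
    """Build D_k(g), collapse tree-like regions, compress paths, and locate
    every node's genome occurrences."""
    g = build_graph(genome, k)
    path_compress_inplace(g)
    collapse_trees_inplace(g)  # interleaves further path compression
    path_compress_inplace(g)
    locate_occurrences(g, genome)
    return g


def genome_decomposition(graph: KmerGraph, genome: Genome) -> list[tuple[int, int]]:
    """The genome's traversal of the graph as a list of (node, occurrence).

    Consecutive elements overlap by k-2 symbols; net lengths sum to the
    genome length.  Cached on the graph.  Backtracking resolves the rare
    case where one node's sequence is a prefix of another's at the same
    position.
    """
    cached = getattr(graph, "_decomposition", None)
    if cached is not None:
        return cached
    n = len(genome)
    o = graph.k - 2
    occ_at: dict[int, list[int]] = {}
    for u in sorted(graph.nodes):
        if graph.nodes[u].occurrences is None:
            raise ValueError("call locate_occurrences before decomposing")
        for p in graph.nodes[u].occurrences:
            occ_at.setdefault(p, []).append(u)

    start_node = min(graph.nodes)
    start_occ = graph.nodes[start_node].occurrences[0]
    circular = genome.circular
    target = n if circular else n - (len(graph.seq(start_node)) - o) - o

    path: list[tuple[int, int]] = [(start_node, start_occ)]

    def net(u: int) -> int:
        return len(graph.seq(u)) - o

    def dfs(cur: int, pos: int, walked: int) -> bool:
        # pos: genome position where the next node must start
        if circular:
            if walked == n:
                return pos % n == start_occ  # the cycle closes
            if walked > n:
                return False
        else:
            if pos + o >= n or not graph.successors(cur):
                return pos + o == n  # trail reaches the genome end
        for w in graph.successors(cur):
            if w in occ_at.get(pos % n if circular else pos, []):
                path.append((w, pos % n if circular else pos))
                if dfs(w, pos + net(w), walked + net(w)):
                    return True
                path.pop()
        return False

    first_net = net(start_node)
    if not dfs(start_node, start_occ + first_net, first_net):
        raise ValueError("genome does not decompose over this graph; "
                         "graph/genome mismatch")
    graph._decomposition = path
    return path


def _start_position(gene: GeneAnnotation, n: int) -> int:
    """0-based genome coordinate of the base mapping to the coding start."""
    return (gene.start - 1) if gene.strand == "+" else (gene.end - 1)


def locate_start_node(graph: KmerGraph, genome: Genome,
                      gene: GeneAnnotation) -> tuple[int, int]:
    """Node whose region contains the gene's coding start, with the offset of
    that base in the node's sequence.

    When the base falls in the k-2 overlap of two consecutive nodes, the
    downstream-extending node is chosen (the net intervals of the genome
    decomposition partition the genome, so the choice is deterministic).
    """
    n = len(genome)
    p = _start_position(gene, n)
    decomp = genome_decomposition(graph, genome)
    o = graph.k - 2
    for idx, (u, occ) in enumerate(decomp):
        net = len(graph.seq(u)) - o
        rel = (p - occ) % n if genome.circular else p - occ
        if 0 <= rel < net:
            return u, rel
    # a linear genome's final o symbols belong only to the last node's tail
    if not genome.circular:
        u, occ = decomp[-1]
        if 0 <= p - occ < len(graph.seq(u)):
            return u, p - occ
    raise ValueError(f"gene {gene.gene_id!r}: coding start at {p} not covered by any node")


def is_reconstructible(graph: KmerGraph, genome: Genome,
                       gene: GeneAnnotation) -> tuple[bool, WalkOutcome]:
    """Walk forward from the gene's start node along the genome's true path
    and test whether the full coding interval fits before the walk crosses a
    backward-then-forward decision pair."""
    n = len(genome)
    o = graph.k - 2
    gs, glen = gene.interval0(n)
    p = _start_position(gene, n)

    try:
        decomp = genome_decomposition(graph, genome)
        start_node, _offset = locate_start_node(graph, genome, gene)
    except ValueError as exc:
        out = WalkOutcome(start_node=-1)
        out.explored_paths.append([])
        return False, out  # unlocatable start: not reconstructible

    # index of the decomposition element owning the coding start
    start_idx = None
    for idx, (u, occ) in enumerate(decomp):
        net = len(graph.seq(u)) - o
        rel = (p - occ) % n if genome.circular else p - occ
        if u == start_node and 0 <= rel < net:
            start_idx = idx
            break
    if start_idx is None:
        start_idx = len(decomp) - 1
    occ0 = decomp[start_idx][1]

    # distance from the walk origin to the last base of the gene interval
    rel_gene_end = ((gs - occ0) % n if genome.circular else gs - occ0) + glen - 1

    path_nodes: list[int] = []
    passed_backward = False
    terminated = False
    walked_net = 0
    m = len(decomp)
    steps = 0
    idx = start_idx
    while True:
        u, occ = decomp[idx]
        path_nodes.append(u)
        walked_net += len(graph.seq(u)) - o
        covered = walked_net + o  # the final node is covered in full
        if graph.in_degree(u) > 1:
            passed_backward = True
        if passed_backward and graph.out_degree(u) > 1:
            terminated = True  # this node's own region is still covered
            break
        if rel_gene_end < covered:
            break  # gene already fits; no need to walk further
        steps += 1
        idx = (idx + 1) % m
        if genome.circular and steps >= 2 * m and walked_net >= n:
            break  # unterminated walk wrapped the whole genome
        if not genome.circular and idx == 0:
            break  # ran off the end of a linear genome

    ok = rel_gene_end < walked_net + o
    if not genome.circular:
        ok = ok and 0 <= gs - occ0  # no wrap available to cover upstream bases
    outcome = WalkOutcome(start_node=start_node)
    outcome.explored_paths.append(path_nodes)
    outcome.passed_backward.append(passed_backward)
    outcome.terminated_at_forward.append(terminated)
    outcome.covered_intervals.append((occ0, walked_net + o))
    return ok, outcome


def summarize_reconstructibility(
        flags: dict[str, tuple[bool, str]],
        annotations: list[GeneAnnotation],
        keywords: tuple[str, ...] = DEFAULT_KEYWORDS) -> GeneReconReport:
    """Fraction of reconstructible genes plus keyword tallies among the
    non-reconstructible, non-"hypothetical" gene descriptions."""
    per_gene = {}
    products = {a.gene_id: a.product for a in annotations}
    for gid, (ok, reason) in flags.items():
        per_gene[gid] = {"reconstructible": ok, "reason": reason}
    total = len(per_gene)
    fraction = (100.0 * sum(1 for v in per_gene.values() if v["reconstructible"]) / total
                if total else None)
    tallies = {kw: 0 for kw in keywords}
    for gid, rec in per_gene.items():
        if rec["reconstructible"]:
            continue
        desc = products.get(gid, "").lower()
        if "hypothetical" in desc:
            continue
        for kw in keywords:
            if kw.lower() in desc:
                tallies[kw] += 1
    return GeneReconReport(per_gene, fraction, tallies)


def analyze_genes(genome: Genome, annotations: list[GeneAnnotation], k: int,
                  keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
                  ) -> tuple[GeneReconReport, KmerGraph]:
    """Full pipeline: prepare the graph, classify every gene, summarize."""
    graph = prepare_recon_graph(genome, k)
    flags = {}
    for gene in annotations:
        ok, outcome = is_reconstructible(graph, genome, gene)
        if ok:
            reason = "contained in unambiguous walk"
        elif outcome.start_node == -1:
            reason = "coding start not locatable"
        elif outcome.terminated_at_forward and outcome.terminated_at_forward[0]:
            reason = "walk blocked by backward-then-forward decision"
        else:
            reason = "interval extends beyond covered region"
        flags[gene.gene_id] = (ok, reason)
    return summarize_reconstructibility(flags, annotations, keywords), graph
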