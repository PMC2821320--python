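"""De Bruijn multigraph of a genome from idealized length-k reads.

The graph D_k(g) has a node for every (k-1)-mer occurring in the genome g and
one directed edge per k-mer occurrence, joining the k-mer's (k-1)-prefix node
to its (k-1)-suffix node.  Parallel edges and self-loops are allowed and are
stored as (u, v) -> multiplicity counters, never as individual edge objects.
Circular genomes wrap k-mers across the origin, so their graphs are Eulerian
balanced; linear genomes may instead have a single imbalanced pair (s, t)
marking the endpoints of every Eulerian trail.

After simplification (see :mod:`asmcomplexity.simplify`) node sequences grow
beyond k-1 symbols, but consecutive spelled units along any edge always
overlap by exactly k-2 symbols; that invariant is what the spelling helpers
here rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import deque

from .genome import Genome

__all__ = [
    "NodeRecord",
    "KmerGraph",
    "BalanceError",
    "build_graph",
    "classify_node",
    "locate_occurrences",
    "merge_seqs",
    "spell_walk",
]


class BalanceError(ValueError):
    """The multigraph violates the Eulerian degree-balance invariant."""


@dataclass
class NodeRecord:
    id: int
    sequence: str
    #: 0-based start positions of `sequence` in the source genome; filled by
    #: :func:`locate_occurrences`, absent until then.
    occurrences: list[int] | None = field(default=None)


def merge_seqs(a: str, b: str, k: int) -> str:
    """Overlap-merge two spelled units sharing k-2 symbols."""
    o = k - 2
    if o and a[-o:] != b[:o]:
        raise ValueError(f"units do not overlap by {o} symbols: ...{a[-o:]!r} vs {b[:o]!r}...")
    return a + b[o:]


def spell_walk(units: list[str], k: int, circuit: bool = False) -> str:
    """Spell a walk given its node/label sequences in traversal order.

    Every unit is emitted with k-2 symbols of overlap removed.  For a circuit
    the final unit (the return to the start node) contributes only its first
    k-1 symbols: the walk ends once the last edge's k-mer has been consumed.
    For a trail the final unit is spelled in full.
    """
    o = k - 2
    if not units:
        return ""
    last = units[-1][: k - 1] if circuit and len(units) > 1 else units[-1]
    parts = [units[0]]
    for unit in units[1:-1]:
        parts.append(unit[o:])
    if len(units) > 1:
        parts.append(last[o:])
    return "".join(parts)


class KmerGraph:
    """Directed multigraph with integer edge multiplicities and node sequences.

    Edges are grouped as (u, v, label) -> multiplicity; ``label`` is ``None``
    except for edges created by non-decision-node-to-edge conversion, which
    carry the spelled sequence of the eliminated node.
    """

    def __init__(self, k: int, topology: str, genome_length: int | None = None):
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        if topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {topology!r}")
        self.k = k
        self.topology = topology
        self.genome_length = genome_length
        self.nodes: dict[int, NodeRecord] = {}
        self._out: dict[int, dict[int, dict[str | None, int]]] = {}
        self._in: dict[int, dict[int, int]] = {}
        #: (s, t) endpoints of the Eulerian trail, or None for circuit graphs.
        self.terminals: tuple[int, int] | None = None
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def new_node(self, sequence: str, node_id: int | None = None) -> int:
        if len(sequence) < self.k - 1:
            raise ValueError(f"node sequence shorter than k-1: {sequence!r}")
        nid = self._next_id if node_id is None else node_id
        if nid in self.nodes:
            raise ValueError(f"duplicate node id {nid}")
        self._next_id = max(self._next_id, nid + 1)
        self.nodes[nid] = NodeRecord(nid, sequence)
        self._out[nid] = {}
        self._in[nid] = {}
        return nid

    def remove_node(self, u: int) -> None:
        if self._out[u] or self._in[u]:
            raise ValueError(f"node {u} still has incident edges")
        del self.nodes[u], self._out[u], self._in[u]

    def add_edge(self, u: int, v: int, mult: int = 1, label: str | None = None) -> None:
        if mult <= 0:
            raise ValueError("edge multiplicity must be positive")
        group = self._out[u].setdefault(v, {})
        group[label] = group.get(label, 0) + mult
        self._in[v][u] = self._in[v].get(u, 0) + mult

    def remove_edge(self, u: int, v: int, mult: int, label: str | None = None) -> None:
        group = self._out[u][v]
        if group.get(label, 0) < mult:
            raise ValueError(f"cannot remove {mult} copies of edge {u}->{v} (label={label!r})")
        group[label] -= mult
        if group[label] == 0:
            del group[label]
        if not group:
            del self._out[u][v]
        self._in[v][u] -= mult
        if self._in[v][u] == 0:
            del self._in[v][u]

    # -- interrogation ----------------------------------------------------

    def seq(self, u: int) -> str:
        return self.nodes[u].sequence

    def successors(self, u: int) -> list[int]:
        return sorted(self._out[u])

    def predecessors(self, v: int) -> list[int]:
        return sorted(self._in[v])

    def multiplicity(self, u: int, v: int) -> int:
        return sum(self._out[u].get(v, {}).values())

    def out_degree(self, u: int) -> int:
        return sum(sum(g.values()) for g in self._out[u].values())

    def in_degree(self, v: int) -> int:
        return sum(self._in[v].values())

    def edge_groups(self):
        """Yield (u, v, label, multiplicity) in deterministic order."""
        for u in sorted(self._out):
            for v in sorted(self._out[u]):
                for label in sorted(self._out[u][v], key=lambda x: (x is not None, x)):
                    yield u, v, label, self._out[u][v][label]

    def total_edges(self) -> int:
        """Total number of edge instances (multiplicities summed)."""
        return sum(m for *_, m in self.edge_groups())

    def visit_count(self, u: int) -> int:
        return max(self.out_degree(u), self.in_degree(u), 1)

    def has_self_loop(self, u: int) -> bool:
        return u in self._out[u]

    # -- invariants --------------------------------------------------------

    def balance(self) -> tuple[int, int] | None:
        """Check Eulerian balance; return the (s, t) pair or None if balanced.

        Raises :class:`BalanceError` when more than one node is imbalanced in
        either direction.
        """
        s = t = None
        for u in sorted(self.nodes):
            diff = self.out_degree(u) - self.in_degree(u)
            if diff == 0:
                continue
            if diff == 1 and s is None:
                s = u
            elif diff == -1 and t is None:
                t = u
            else:
                raise BalanceError(f"node {u} has degree imbalance {diff} (graph not Eulerian)")
        if (s is None) != (t is None):
            raise BalanceError("exactly one of s, t imbalanced")
        return None if s is None else (s, t)

    def is_connected(self) -> bool:
        """Weak connectivity of the subgraph induced by nodes with edges."""
        active = [u for u in self.nodes if self._out[u] or self._in[u]]
        if len(active) <= 1:
            return True
        seen = {active[0]}
        queue = deque(seen)
        while queue:
            u = queue.popleft()
            for v in list(self._out[u]) + list(self._in[u]):
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return all(u in seen for u in active)

    def copy(self) -> "KmerGraph":
        g = KmerGraph(self.k, self.topology, self.genome_length)
        g.terminals = self.terminals
        g._next_id = self._next_id
        for u, rec in self.nodes.items():
            g.nodes[u] = NodeRecord(u, rec.sequence, None if rec.occurrences is None else list(rec.occurrences))
            g._out[u] = {}
            g._in[u] = {}
        for u, v, label, mult in self.edge_groups():
            g.add_edge(u, v, mult, label)
        return g

    def __repr__(self) -> str:
        return (f"KmerGraph(k={self.k}, {self.topology}, nodes={len(self.nodes)}, "
                f"edges={self.total_edges()})")


def build_graph(genome: Genome, k: int) -> KmerGraph:
    """Build the de Bruijn multigraph D_k(g) of a genome.

    Circular genomes contribute one k-mer per position (wrapping the origin),
    so the total edge multiplicity equals the genome length; linear genomes
    contribute len(g) - k + 1 k-mers.
    """
    n = len(genome)
    if genome.circular:
        if n < k - 1:
            raise ValueError(f"circular genome of length {n} too short for k={k}")
        text = genome.sequence * (2 + k // max(n, 1))
        kmers = [text[i:i + k] for i in range(n)]
    else:
        if n < k:
            raise ValueError(f"linear genome of length {n} too short for k={k}")
        kmers = [genome.sequence[i:i + k] for i in range(n - k + 1)]

    mers = sorted({km[:-1] for km in kmers} | {km[1:] for km in kmers})
    g = KmerGraph(k, genome.topology, genome_length=n)
    ids = {}
    for rank, mer in enumerate(mers):  # lexicographic rank = node id
        ids[mer] = g.new_node(mer, rank)
    from collections import Counter
    for (pre, suf), mult in sorted(Counter((km[:-1], km[1:]) for km in kmers).items()):
        g.add_edge(ids[pre], ids[suf], mult)
    g.terminals = g.balance()
    return g


def classify_node(graph: KmerGraph, u: int) -> str:
    """Degree-based decision classification; parallel edges count toward degree."""
    if u not in graph.nodes:
        raise KeyError(f"unknown node id {u}")
    fwd = graph.out_degree(u) > 1
    bwd = graph.in_degree(u) > 1
    if fwd and bwd:
        return "full_decision"
    if fwd:
        return "forward_decision"
    if bwd:
        return "backward_decision"
    return "non_decision"


def _find_occurrences(seq: str, genome: Genome) -> list[int]:
    g = genome.sequence
    n = len(g)
    if genome.circular:
        text = g * (2 + len(seq) // n)
        return [i for i in range(n) if text.startswith(seq, i)]
    return [i for i in range(n - len(seq) + 1) if g.startswith(seq, i)]


def locate_occurrences(graph: KmerGraph, genome: Genome) -> KmerGraph:
    """Fill every node's list of 0-based occurrence starts in the genome.

    Raises ValueError when a node sequence is absent, which signals that the
    graph was not derived from this genome.
    """
    for u in sorted(graph.nodes):
        occ = _find_occurrences(graph.seq(u), genome)
        if not occ:
            raise ValueError(f"node {u} sequence not found in genome {genome.id!r}")
        graph.nodes[u].occurrences = occ
    return graph
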