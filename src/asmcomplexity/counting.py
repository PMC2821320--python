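"""Counting genome reconstructions consistent with a de Bruijn graph.

The number of distinct words spellable from an Eulerian multigraph G ending
at a node t is

    W(G, t) = det(L with row and column t deleted)
              * prod_u (r_u - 1)!  /  prod_{(u,v)} a_uv!

where a_uv are the edge multiplicities, r_u = d+(u) (+1 for u = t), and L has
r_u - a_uu on the diagonal and -a_uv off it.  This is the BEST-theorem
arborescence count with two corrections: parallel edges are interchangeable
(the division), and trails as well as circuits are allowed (the +1 at t).
Dividing further by d+(t) turns linear words ending at t into cyclic
reconstructions of a circular genome, valid whenever the graph is not
periodic.

Exact arithmetic uses arbitrary-precision integers with a fraction-free
(Bareiss) determinant via sympy; counts in real genomes reach the 2^900
scale, so a log2 mode evaluates the same expression in log space with a
floating-point LU determinant and log-factorials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import sympy

from .graph import KmerGraph, BalanceError

__all__ = [
    "CountMatrixBundle",
    "WordCountResult",
    "PeriodicGraphError",
    "build_count_matrix",
    "count_words",
    "count_eulerian_trails",
    "count_circular",
    "detect_periodicity",
    "reduce_for_counting",
]


def reduce_for_counting(graph: KmerGraph) -> KmerGraph:
    """Shrink a graph without changing its reconstruction counts.

    Path compression and tree-like-region collapse preserve the word set
    exactly and never duplicate a node sequence, so W(G, t) for trail graphs
    and W(G, t)/d+(t) for circuit graphs are unchanged while the count
    matrix shrinks from one row per (k-1)-mer to one row per surviving
    (mostly decision) node.  Half-decision splitting is deliberately NOT
    applied: it duplicates node sequences, after which distinct node
    orderings can spell the same word and the determinant formula would
    overcount.
    """
    from .simplify import path_compress_inplace, collapse_trees_inplace
    g = graph.copy()
    path_compress_inplace(g)
    collapse_trees_inplace(g)
    return g

#: above this many nodes exact determinants are refused by default
EXACT_NODE_LIMIT = 2000


class PeriodicGraphError(ValueError):
    """Cyclic word counting is undefined for (possibly) periodic graphs."""


@dataclass
class CountMatrixBundle:
    node_order: list[int]
    L: list[list[int]]
    r: dict[int, int]
    t: int


@dataclass
class WordCountResult:
    exact_count: int | None
    log2_count: float
    mode: str  # "trail" | "circuit"
    circular_corrected: bool = False
    periodic: str = "possibly"  # "no" | "possibly" | "yes"


def _active_nodes(graph: KmerGraph) -> list[int]:
    active = sorted(u for u in graph.nodes
                    if graph.out_degree(u) or graph.in_degree(u))
    return active if active else sorted(graph.nodes)


def build_count_matrix(graph: KmerGraph, t: int | None = None) -> CountMatrixBundle:
    """Populate L and r for a chosen terminal node t.

    For a balanced graph t is arbitrary (auto = lowest active node id); for a
    trail graph t is forced to the unique node with d+(t) = d-(t) - 1 and an
    explicit conflicting choice is an error.
    """
    terms = graph.balance()  # raises BalanceError beyond one (s, t) pair
    if terms is not None:
        if t is not None and t != terms[1]:
            raise ValueError(f"t={t} conflicts with the forced trail end t={terms[1]}")
        t = terms[1]
    elif t is None:
        t = _active_nodes(graph)[0]
    elif t not in graph.nodes:
        raise KeyError(f"unknown node id {t}")

    order = _active_nodes(graph)
    r = {u: graph.out_degree(u) + (1 if u == t else 0) for u in order}
    L = [[(r[u] - graph.multiplicity(u, u)) if u == v else -graph.multiplicity(u, v)
          for v in order] for u in order]
    return CountMatrixBundle(order, L, r, t)


def _minor(L: list[list[int]], idx: int) -> list[list[int]]:
    return [[x for j, x in enumerate(row) if j != idx]
            for i, row in enumerate(L) if i != idx]


def _exact_det(M: list[list[int]]) -> int:
    if not M:
        return 1
    return int(sympy.Matrix(M).det(method="bareiss"))


def _edge_group_mults(graph: KmerGraph) -> list[int]:
    # Parallel edges are interchangeable only within a (u, v, label) group:
    # distinct labels spell distinct words.
    return [mult for *_, mult in graph.edge_groups()]


def count_words(graph: KmerGraph, t: int | None = None,
                mode: str = "exact") -> WordCountResult:
    """Number of distinct words consistent with the graph ending at node t."""
    if not graph.nodes:
        raise ValueError("empty graph")
    if mode not in ("exact", "log2"):
        raise ValueError(f"mode must be exact or log2, got {mode!r}")
    bundle = build_count_matrix(graph, t)
    walk_mode = "circuit" if graph.balance() is None else "trail"
    periodic = detect_periodicity(graph, quick=True) if walk_mode == "circuit" else "no"
    idx = bundle.node_order.index(bundle.t)
    minor = _minor(bundle.L, idx)
    mults = _edge_group_mults(graph)

    if mode == "exact":
        if len(bundle.node_order) > EXACT_NODE_LIMIT:
            raise ValueError(f"graph too large for exact mode "
                             f"({len(bundle.node_order)} > {EXACT_NODE_LIMIT} nodes); use log2")
        num = _exact_det(minor)
        for u in bundle.node_order:
            num *= math.factorial(bundle.r[u] - 1)
        den = 1
        for m in mults:
            den *= math.factorial(m)
        if num % den:
            raise ArithmeticError("word count is not integral; graph invalid")
        w = num // den
        log2 = math.log2(w) if w > 0 else float("-inf")
        return WordCountResult(w, log2, walk_mode, periodic=periodic)

    if not minor:
        logdet = 0.0
    else:
        sign, logabs = np.linalg.slogdet(np.array(minor, dtype=float))
        if sign <= 0:
            raise ArithmeticError("non-positive determinant in log2 mode")
        logdet = logabs / math.log(2)
    log2 = logdet
    log2 += sum(math.lgamma(bundle.r[u]) for u in bundle.node_order) / math.log(2)
    log2 -= sum(math.lgamma(m + 1) for m in mults) / math.log(2)
    return WordCountResult(None, log2, walk_mode, periodic=periodic)


def count_eulerian_trails(graph: KmerGraph) -> int:
    """Eulerian trails (or circuits from the lowest node), parallel edge
    instances distinguishable, by the BEST-theorem arborescence formula."""
    if not graph.nodes:
        raise ValueError("empty graph")
    if not graph.is_connected():
        raise ValueError("graph is disconnected; no Eulerian traversal exists")
    if graph.total_edges() == 0:
        return 1
    terms = graph.balance()
    g = graph
    if terms is not None:
        g = graph.copy()
        g.add_edge(terms[1], terms[0])  # close the trail into a circuit
        g.terminals = None
    active = _active_nodes(g)
    root = active[0]
    # in-tree count: det of the out-degree Laplacian minor (identical at
    # every root of a connected Eulerian digraph)
    lap = [[(g.out_degree(u) - g.multiplicity(u, u)) if u == v
            else -g.multiplicity(u, v) for v in active] for u in active]
    tw = _exact_det(_minor(lap, active.index(root)))
    count = tw
    for u in active:
        count *= math.factorial(g.out_degree(u) - 1)
    if terms is None:
        count *= g.out_degree(root)  # linearize circuits at a fixed start
    return count


def detect_periodicity(graph: KmerGraph, max_edges: int = 14,
                       quick: bool = False) -> str:
    """Decide whether the graph is periodic (traversable as a c-fold repeat).

    Any node visited exactly once pins the rotation, so the graph cannot be
    periodic ("no").  Otherwise small graphs are checked exhaustively: a
    circuit whose node sequence has a nontrivial cyclic period exhibits the
    repeat ("yes").  Larger all-repeated graphs report "possibly".
    """
    if graph.balance() is not None:
        return "no"  # trail graphs have fixed endpoints, never periodic
    active = _active_nodes(graph)
    if min(max(graph.out_degree(u), 1) for u in active) == 1:
        return "no"
    if quick or graph.total_edges() > max_edges:
        return "possibly"

    remaining = {(u, v): graph.multiplicity(u, v)
                 for u, v, label, _ in graph.edge_groups()}
    total = graph.total_edges()
    start = active[0]
    path = [start]
    found = False

    def period_of(seq: list[int]) -> int:
        n = len(seq)
        for p in range(1, n + 1):
            if n % p == 0 and all(seq[i] == seq[(i + p) % n] for i in range(n)):
                return p
        return n

    def dfs(cur: int, used: int):
        nonlocal found
        if found:
            return
        if used == total:
            if cur == start and period_of(path[:-1]) < len(path) - 1:
                found = True
            return
        for v in graph.successors(cur):
            if remaining.get((cur, v), 0) > 0:
                remaining[(cur, v)] -= 1
                path.append(v)
                dfs(v, used + 1)
                path.pop()
                remaining[(cur, v)] += 1

    dfs(start, 0)
    return "yes" if found else "no"


def count_circular(graph: KmerGraph, t: int | None = None, mode: str = "exact",
                   assume_aperiodic: bool = False) -> WordCountResult:
    """Cyclically distinct reconstructions of a circular genome: W(G,t)/d+(t).

    Valid only for non-periodic circuit graphs; the divisibility of W by
    d+(t) is asserted, and the result is independent of the choice of t.
    """
    if graph.balance() is not None:
        raise ValueError("circular counting needs a balanced (circuit) graph")
    periodic = detect_periodicity(graph)
    if periodic != "no" and not assume_aperiodic:
        raise PeriodicGraphError(
            f"graph periodicity is {periodic!r}; W/d+(t) does not count cyclic words")
    if t is None:
        t = _active_nodes(graph)[0]
    res = count_words(graph, t, mode=mode)
    d = graph.out_degree(t)
    if res.exact_count is not None:
        if res.exact_count % d:
            raise ArithmeticError(
                f"W={res.exact_count} not divisible by d+(t)={d}; periodicity fault")
        w = res.exact_count // d
        log2 = math.log2(w) if w > 0 else float("-inf")
        return WordCountResult(w, log2, "circuit", True, periodic)
    return WordCountResult(None, res.log2_count - math.log2(d), "circuit", True, periodic)
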