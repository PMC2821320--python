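"""Synthetic genomes with planted repeats, and a brute-force Eulerian oracle.

The generator builds circular genomes whose only k-mer-level ambiguity is the
planted repeat structure: the random background is rejection-sampled until it
is repeat-free at a declared uniqueness length.  The oracle exhaustively
enumerates Eulerian trails/circuits by backtracking, spelling each one, and is
deliberately exponential: it exists to validate the polynomial-time counting
and the information-preserving simplifications on small instances, never for
production use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import Genome, GeneAnnotation
from .graph import KmerGraph, spell_walk

__all__ = [
    "RepeatFamily",
    "GeneSpec",
    "SimSpec",
    "OracleResult",
    "generate_genome",
    "random_genome",
    "enumerate_words",
    "canonical_rotation",
]

ORACLE_MAX_EDGES = 14


@dataclass(frozen=True)
class RepeatFamily:
    """A planted repeat: `copies` exact copies of one random `length`-mer."""
    length: int
    copies: int
    arrangement: str = "interspersed"  # or "tandem": copies placed adjacently

    def __post_init__(self):
        if self.copies < 2:
            raise ValueError("a repeat family needs at least 2 copies")
        if self.arrangement not in ("interspersed", "tandem"):
            raise ValueError(f"bad arrangement {self.arrangement!r}")


@dataclass(frozen=True)
class GeneSpec:
    """A toy gene annotation to plant; `start` is 0-based."""
    start: int
    length: int
    strand: str = "+"
    product: str = "predicted protein"


@dataclass(frozen=True)
class SimSpec:
    genome_length: int
    seed: int
    repeat_families: tuple[RepeatFamily, ...] = ()
    gene_layout: tuple[GeneSpec, ...] = ()
    alphabet: str = "ACGT"
    #: background is guaranteed repeat-free at this k; tests should use k
    #: values >= this so planted repeats are the only ambiguity.
    uniqueness_k: int = 12

    def __post_init__(self):
        total = sum(f.length * f.copies for f in self.repeat_families)
        if total >= self.genome_length:
            raise ValueError("planted repeats exceed the genome length")
        for gs in self.gene_layout:
            if not (0 <= gs.start < self.genome_length) or gs.length < 1:
                raise ValueError(f"gene at {gs.start} outside genome bounds")
            if gs.length > self.genome_length:
                raise ValueError("gene longer than genome")


def _random_string(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _circular_kmer_positions(g: str, k: int) -> dict[str, list[int]]:
    text = g * (2 + k // max(len(g), 1))
    pos: dict[str, list[int]] = {}
    for i in range(len(g)):
        pos.setdefault(text[i:i + k], []).append(i)
    return pos


def _intersects(i: int, kmer_len: int, intervals: list[tuple[int, int]], n: int) -> bool:
    """Does the circular k-mer starting at i overlap any planted interval?"""
    for (a, ln) in intervals:
        for shift in (0, n, -n):
            if i + shift < a + ln and a < i + shift + kmer_len:
                return True
    return False


def generate_genome(spec: SimSpec) -> tuple[Genome, list[GeneAnnotation], dict]:
    """Build a circular genome with exact planted repeat copies.

    Returns the genome, the annotations from ``spec.gene_layout``, and a
    manifest recording every planted copy's 0-based position.  Deterministic
    given the seed; raises if a valid layout cannot be sampled.
    """
    rng = np.random.default_rng(spec.seed)
    n, ku = spec.genome_length, spec.uniqueness_k
    min_spacer = max(1, min(ku, max(1, (n - sum(f.length * f.copies for f in spec.repeat_families)) // max(1, sum(f.copies for f in spec.repeat_families)))))

    for _attempt in range(200):
        fams = [_random_string(rng, spec.alphabet, f.length) for f in spec.repeat_families]
        slots: list[tuple[int, str]] = []  # (family index, sequence to insert)
        for idx, fam in enumerate(spec.repeat_families):
            if fam.arrangement == "tandem":
                slots.append((idx, fams[idx] * fam.copies))
            else:
                slots.extend((idx, fams[idx]) for _ in range(fam.copies))
        order = list(rng.permutation(len(slots))) if slots else []
        slots = [slots[i] for i in order]

        bg_len = n - sum(len(s) for _, s in slots)
        nchunks = max(len(slots), 1)
        if bg_len < nchunks * min_spacer:
            raise ValueError("genome too short for the requested repeat families")
        extra = rng.multinomial(bg_len - nchunks * min_spacer, [1 / nchunks] * nchunks)
        chunk_sizes = [min_spacer + int(e) for e in extra]

        pieces, intervals, positions = [], [], {i: [] for i in range(len(spec.repeat_families))}
        at = 0
        for j, size in enumerate(chunk_sizes):
            pieces.append(_random_string(rng, spec.alphabet, size))
            at += size
            if j < len(slots):
                idx, s = slots[j]
                fam = spec.repeat_families[idx]
                if fam.arrangement == "tandem":
                    positions[idx].extend(at + c * fam.length for c in range(fam.copies))
                else:
                    positions[idx].append(at)
                intervals.append((at, len(s)))
                pieces.append(s)
                at += len(s)
        g = "".join(pieces)
        assert len(g) == n

        # planted copies must be exact and exclusive: every duplicated
        # uniqueness-k-mer must be attributable to a planted interval.
        ok = True
        for idx, fam in enumerate(spec.repeat_families):
            found = [i for i in range(n) if (g * 2).startswith(fams[idx], i)]
            if len(found) != fam.copies:
                ok = False
                break
        if ok and n >= ku:
            for kmer, occs in _circular_kmer_positions(g, ku).items():
                if len(occs) > 1 and not all(_intersects(i, ku, intervals, n) for i in occs):
                    ok = False
                    break
        if ok:
            genome = Genome("sim", g, "circular", alphabet=spec.alphabet)
            annots = [
                GeneAnnotation(
                    gene_id=f"g{i + 1}",
                    start=gs.start + 1,
                    end=(gs.start + gs.length - 1) % n + 1,
                    strand=gs.strand,
                    product=gs.product,
                )
                for i, gs in enumerate(spec.gene_layout)
            ]
            manifest = {
                "seed": spec.seed,
                "genome_length": n,
                "repeats": [
                    {
                        "family": idx,
                        "sequence": fams[idx],
                        "length": spec.repeat_families[idx].length,
                        "copies": spec.repeat_families[idx].copies,
                        "arrangement": spec.repeat_families[idx].arrangement,
                        "positions": sorted(positions[idx]),
                    }
                    for idx in range(len(spec.repeat_families))
                ],
            }
            return genome, annots, manifest
    raise RuntimeError("could not sample a genome satisfying the repeat spec; "
                       "try a longer genome or a smaller uniqueness_k")


def random_genome(length: int, seed: int, alphabet: str = "ACGT",
                  topology: str = "circular", gid: str = "rand") -> Genome:
    """Uniform random genome (no uniqueness guarantee) for stress tests.

    Small lengths over small alphabets naturally contain repeats, which makes
    these the workhorse inputs for the exhaustive-oracle equivalence suites.
    """
    rng = np.random.default_rng(seed)
    return Genome(gid, _random_string(rng, alphabet, length), topology, alphabet=alphabet)


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    """Exhaustive enumeration of Eulerian trails/circuits and their spellings.

    `trails` counts edge sequences with parallel edge instances treated as
    distinguishable (trails s->t for trail graphs; circuits from the lowest
    active node for circuit graphs).  `distinct_words` are the spelled words
    from that same endpoint; `words_by_end` maps every possible final node t
    to the set of words ending with t; `cyclic_words` canonicalizes circuit
    words up to rotation (None for trail graphs).
    """
    mode: str
    trails: int
    distinct_words: set[str]
    words_by_end: dict[int, set[str]]
    cyclic_words: set[str] | None = None

    @property
    def distinct_count(self) -> int:
        return len(self.distinct_words)


def canonical_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s))) if s else s


def _enumerate_from(graph: KmerGraph, start: int, end: int) -> tuple[int, set[str], bool]:
    """All Eulerian walks start->end consuming every edge; returns
    (#node/label sequences, spelled words, is_circuit)."""
    remaining = {}
    for u, v, label, mult in graph.edge_groups():
        remaining[(u, v, label)] = mult
    total = sum(remaining.values())
    k = graph.k
    is_circuit = start == end and total > 0
    nseq = 0
    words: set[str] = set()
    units = [graph.seq(start)]

    def dfs(cur: int, used: int):
        nonlocal nseq
        if used == total:
            if cur == end:
                nseq += 1
                words.add(spell_walk(units, k, circuit=is_circuit))
            return
        for v in graph.successors(cur):
            for label in sorted(graph._out[cur][v], key=lambda x: (x is not None, x)):
                key = (cur, v, label)
                if remaining.get(key, 0) > 0:
                    remaining[key] -= 1
                    if label is not None:
                        units.append(label)
                    units.append(graph.seq(v))
                    dfs(v, used + 1)
                    units.pop()
                    if label is not None:
                        units.pop()
                    remaining[key] += 1

    dfs(start, 0)
    return nseq, words, is_circuit


def enumerate_words(graph: KmerGraph, max_edges: int = ORACLE_MAX_EDGES) -> OracleResult:
    """Enumerate all Eulerian trails/circuits of a small graph and spell them.

    Parallel edge instances are distinguishable, so the trail count for a
    graph with node/label-sequence count S is S * prod(mult!) over parallel
    groups.  Refuses graphs with more than `max_edges` edge instances.
    """
    total = graph.total_edges()
    if total > max_edges:
        raise ValueError(f"graph has {total} edge instances; oracle capped at {max_edges}")
    perm = 1
    for *_, mult in graph.edge_groups():
        perm *= math.factorial(mult)

    if total == 0:
        (only,) = graph.nodes
        word = graph.seq(only)
        return OracleResult("trail", 1, {word}, {only: {word}})

    terms = graph.balance()
    active = sorted(u for u in graph.nodes if graph.out_degree(u) or graph.in_degree(u))
    if terms is not None:
        s, t = terms
        nseq, words, _ = _enumerate_from(graph, s, t)
        return OracleResult("trail", nseq * perm, words, {t: words})

    words_by_end: dict[int, set[str]] = {}
    trails = None
    k = graph.k
    cyclic: set[str] = set()
    for t in active:
        nseq, words, _ = _enumerate_from(graph, t, t)
        words_by_end[t] = words
        if trails is None:
            trails = nseq * perm  # circuits from the lowest active node
        for w in words:
            cyclic.add(canonical_rotation(w[: len(w) - (k - 1)]))
    t0 = active[0]
    return OracleResult("circuit", trails, words_by_end[t0], words_by_end, cyclic)
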