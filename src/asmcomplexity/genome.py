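"""Domain types: genomes and gene annotations.

Coordinates are 1-based inclusive in external formats (.ptt, GFF3) and in
:class:`GeneAnnotation`; every internal computation converts to 0-based
half-open at the boundary and stays there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = "ACGT"


class AlphabetError(ValueError):
    """A sequence symbol falls outside the declared alphabet."""


@dataclass(frozen=True)
class Genome:
    """A named sequence with explicit circular/linear topology.

    Parameters
    ----------
    id : str
        Record identifier.
    sequence : str
        Uppercased symbol string, length >= 1.
    topology : {"circular", "linear"}
        Never inferred; the caller must state it.
    alphabet : str or None
        Declared alphabet (default ACGT). ``None`` admits arbitrary
        single-character symbols, which toy examples over e.g. {s, a, b} need.
    """

    id: str
    sequence: str
    topology: str
    alphabet: str | None = DNA_ALPHABET

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular or linear, got {self.topology!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        if self.alphabet is not None:
            allowed = set(self.alphabet)
            for pos, sym in enumerate(self.sequence):
                if sym not in allowed:
                    raise AlphabetError(
                        f"genome {self.id!r}: symbol {sym!r} at position {pos} "
                        f"not in alphabet {self.alphabet!r}"
                    )

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A protein-coding gene location in 1-based inclusive coordinates.

    ``end < start`` is legal only for genes wrapping the origin of a circular
    molecule; such annotations carry ``wraps_origin=True``.
    """

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    wraps_origin: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id!r}: start must be >= 1, got {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -, got {self.strand!r}")
        if self.end < self.start:
            self.wraps_origin = True

    def length(self, genome_length: int | None = None) -> int:
        """Gene length in symbols; wrapping genes need the genome length."""
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("genome_length required for an origin-wrapping gene")
        return genome_length - self.start + 1 + self.end

    def interval0(self, genome_length: int | None = None) -> tuple[int, int]:
        """0-based (start, length) of the forward-strand interval."""
        return self.start - 1, self.length(genome_length)
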