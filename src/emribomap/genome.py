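"""Circular genome container and basic sequence arithmetic.

The mitochondrial genome is a covalently closed circle; every coordinate
operation in this package is therefore modular in the genome length L.
The genome is represented linearized from a fixed origin, and all
coordinates are 0-based positions on that linearization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = "ACGT"
VALID_CHARS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def as_ribo(dna_base: str) -> str:
    """Ribo identity of a DNA base: T is reported as U, others unchanged."""
    return "U" if dna_base == "T" else dna_base


def as_dna(ribo_base: str) -> str:
    """DNA base underlying a ribo identity (U -> T)."""
    return "T" if ribo_base == "U" else ribo_base


@dataclass(frozen=True)
class CircularGenome:
    """A named sequence with circular topology.

    Parameters
    ----------
    name : contig identifier used in FASTA/BED output.
    sequence : uppercase string over {A,C,G,T,N} (N only after masking).
    circular : topology flag; the mitochondrial contig is circular, NUMT
        carrier contigs are linear.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        if not set(self.sequence) <= VALID_CHARS:
            bad = sorted(set(self.sequence) - VALID_CHARS)
            raise ValueError(f"invalid characters in sequence: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Forward-strand base at a (mod-L for circular) position."""
        if self.circular:
            return self.sequence[pos % self.length]
        return self.sequence[pos]

    def fetch(self, start: int, length: int) -> str:
        """Substring of given length starting at `start`, wrapping the
        origin when the genome is circular."""
        L = self.length
        if length > L:
            raise ValueError("requested segment longer than genome")
        if self.circular:
            start %= L
            end = start + length
            if end <= L:
                return self.sequence[start:end]
            return self.sequence[start:] + self.sequence[: end - L]
        if start < 0 or start + length > L:
            raise ValueError("segment out of bounds on linear contig")
        return self.sequence[start : start + length]
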