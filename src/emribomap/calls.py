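"""Embedded-ribonucleotide calls from reconciled 5'-end alignments.

RNase H2 cleaves the ribo-containing strand immediately 5' of the embedded
ribonucleotide; the sequenced read initiates at the nick on the opposite
strand. The ribo therefore sits one nucleotide upstream of, and on the
opposite strand to, the read's 5' mapped end:

* plus-strand read with 5' end p  -> site at (p-1) mod L on the minus
  strand, base = complement of the forward base (T reported as U);
* minus-strand read with 5' end p -> site at (p+1) mod L on the plus
  strand, base = forward base (T reported as U).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genome import CircularGenome, as_ribo, complement_base
from .reads import ReadAlignment


@dataclass(frozen=True)
class RiboSite:
    position: int
    strand: str
    base: str  # A/C/G/U on the site's own strand
    mapq: int = 0
    read_id: str = ""

    def key(self) -> tuple[int, str, str]:
        return (self.position, self.strand, self.base)


def filter_mapq(alignments: list[ReadAlignment], threshold: int = 30) -> tuple[list[ReadAlignment], int]:
    """Keep alignments with MAPQ >= threshold (boundary inclusive);
    returns (kept, n_removed)."""
    kept = [a for a in alignments if a.mapq >= threshold]
    return kept, len(alignments) - len(kept)


def call_ribo(alignment: ReadAlignment, genome: CircularGenome) -> RiboSite | None:
    """Infer the embedded-ribo site from one alignment in the
    mitochondrial frame; None when the inferred position is N-masked."""
    L = genome.length
    p = alignment.five_prime_pos
    if alignment.strand == "+":
        pos = (p - 1) % L
        fwd = genome.base(pos)
        if fwd == "N":
            return None
        return RiboSite(pos, "-", as_ribo(complement_base(fwd)), alignment.mapq, alignment.read_id)
    pos = (p + 1) % L
    fwd = genome.base(pos)
    if fwd == "N":
        return None
    return RiboSite(pos, "+", as_ribo(fwd), alignment.mapq, alignment.read_id)


def call_sites(alignments: list[ReadAlignment], genome: CircularGenome) -> tuple[list[RiboSite], int]:
    """Call every alignment; returns (sites, n_dropped_on_N). Multiple
    reads at the same nick stay separate records (aggregation is a
    statistics concern)."""
    sites: list[RiboSite] = []
    n_dropped = 0
    for a in alignments:
        site = call_ribo(a, genome)
        if site is None:
            n_dropped += 1
        else:
            sites.append(site)
    return sites, n_dropped


_STRAND_ORDER = {"+": 0, "-": 1}


def write_sites_bed(path: str | Path, sites: list[RiboSite], chrom: str) -> None:
    """BED6 sites: single-base half-open intervals, name = ribo base,
    score = MAPQ, sorted by position then strand (+ before -)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for s in sorted(sites, key=lambda s: (s.position, _STRAND_ORDER[s.strand])):
            fh.write(f"{chrom}\t{s.position}\t{s.position + 1}\t{s.base}\t{s.mapq}\t{s.strand}\n")


def read_sites_bed(path: str | Path) -> list[RiboSite]:
    sites: list[RiboSite] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _chrom, start, _end, name, score, strand = line.rstrip("\n").split("\t")
            sites.append(RiboSite(int(start), strand, name, int(score)))
    return sites
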