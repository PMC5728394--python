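"""Read placement on the dual reference.

Single-end reads are adapter-clipped, placed independently on the linear
and junction reference versions, and the placement with the higher mapping
quality is retained per read (ties go to the linear version). Junction
placements are lifted back into the mitochondrial coordinate frame, so a
read spanning the circularization origin reports a mod-L 5' coordinate.

Synthetic reads are error-free by construction, so the internal aligner is
exact-substring only (unique placement -> MAPQ 60, multiple -> MAPQ 0);
real libraries enter through SAM ingest from any external aligner.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .genome import revcomp
from .refprep import JUNCTION_NAME, MaskedReference

MAPQ_UNIQUE = 60
MAPQ_MULTI = 0
_SEED_K = 16


@dataclass(frozen=True)
class ReadAlignment:
    """A placed read. ``five_prime_pos`` is the 0-based coordinate of the
    read's 5'-most aligned base on ``contig`` (for minus-strand reads the
    rightmost aligned base)."""

    read_id: str
    contig: str
    strand: str
    five_prime_pos: int
    mapq: int
    source: str  # 'linear' | 'junction' | 'external'


@dataclass
class TrimStats:
    n_input: int = 0
    n_trimmed: int = 0
    n_discarded: int = 0
    n_untouched: int = 0


def trim_adapter(
    sequence: str,
    quality: str,
    adapter: str,
    min_overlap: int = 12,
    min_length: int = 30,
) -> tuple[str, str] | None:
    """Clip a 3' adapter: remove the longest read suffix that exactly
    matches a prefix of the adapter with at least ``min_overlap`` bases.
    Returns the (possibly shortened) read, or None when the trimmed read
    falls below ``min_length`` and is discarded. Reads with no qualifying
    match are returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    best = 0
    for k in range(min(len(sequence), len(adapter)), min_overlap - 1, -1):
        if sequence.endswith(adapter[:k]):
            best = k
            break
    if best == 0:
        return sequence, quality
    new_len = len(sequence) - best
    if new_len < min_length:
        return None
    return sequence[:new_len], quality[:new_len]


def trim_reads(
    records: list[tuple[str, str, str]],
    adapter: str,
    min_overlap: int = 12,
    min_length: int = 30,
) -> tuple[list[tuple[str, str, str]], TrimStats]:
    stats = TrimStats(n_input=len(records))
    kept: list[tuple[str, str, str]] = []
    for rid, seq, qual in records:
        res = trim_adapter(seq, qual, adapter, min_overlap, min_length)
        if res is None:
            stats.n_discarded += 1
            continue
        new_seq, new_qual = res
        if len(new_seq) < len(seq):
            stats.n_trimmed += 1
        else:
            stats.n_untouched += 1
        kept.append((rid, new_seq, new_qual))
    return kept, stats


class ExactAligner:
    """Exact-substring placement over a contig set, seeded on the first
    ``_SEED_K`` bases of each read for speed. Finds every occurrence on
    both strands of every contig."""

    def __init__(self, contigs: dict[str, str]):
        self.contigs = contigs
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in contigs.items():
            for i in range(len(seq) - _SEED_K + 1):
                self._index[seq[i : i + _SEED_K]].append((name, i))

    def placements(self, read: str) -> list[tuple[str, int, str]]:
        """All (contig, five_prime_pos, strand) exact placements."""
        if len(read) < _SEED_K:
            return []
        out: list[tuple[str, int, str]] = []
        n = len(read)
        for contig, pos in self._index.get(read[:_SEED_K], ()):
            if self.contigs[contig][pos : pos + n] == read:
                out.append((contig, pos, "+"))
        rc = revcomp(read)
        for contig, pos in self._index.get(rc[:_SEED_K], ()):
            if self.contigs[contig][pos : pos + n] == rc:
                out.append((contig, pos + n - 1, "-"))
        out.sort()
        return out


@dataclass
class AlignStats:
    n_input: int = 0
    n_unique: int = 0
    n_multi: int = 0
    n_unplaced: int = 0


def align_exact(
    records: list[tuple[str, str, str]],
    reference: MaskedReference,
) -> tuple[dict[str, list[ReadAlignment]], dict[str, AlignStats]]:
    """Place reads on both reference versions. Returns per-version
    alignment lists keyed 'linear' and 'junction', with per-version stats.
    Uniquely placed reads get MAPQ 60; multiply placed reads keep their
    first placement at MAPQ 0; unplaced reads are dropped and counted."""
    versions = {
        "linear": ExactAligner(reference.linear_contigs()),
        "junction": ExactAligner(reference.junction_contigs()),
    }
    out: dict[str, list[ReadAlignment]] = {}
    stats: dict[str, AlignStats] = {}
    for version, aligner in versions.items():
        alns: list[ReadAlignment] = []
        st = AlignStats(n_input=len(records))
        for rid, seq, _qual in records:
            hits = aligner.placements(seq)
            if not hits:
                st.n_unplaced += 1
                continue
            mapq = MAPQ_UNIQUE if len(hits) == 1 else MAPQ_MULTI
            if len(hits) == 1:
                st.n_unique += 1
            else:
                st.n_multi += 1
            contig, pos, strand = hits[0]
            alns.append(ReadAlignment(rid, contig, strand, pos, mapq, version))
        out[version] = alns
        stats[version] = st
    return out, stats


def ingest_sam(path: str | Path, reference: MaskedReference) -> tuple[list[ReadAlignment], int]:
    """Convert primary SAM/BAM alignments to ReadAlignment records.

    The 5' end is the first *aligned* base (soft clips do not shift it
    further): reference_start for plus-strand reads, the rightmost aligned
    base for minus-strand reads. Junction-contig placements are lifted to
    the mitochondrial frame. Returns (alignments, n_unmapped_skipped).
    """
    known = set(reference.linear_contigs()) | {JUNCTION_NAME}
    alns: list[ReadAlignment] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                n_skipped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                continue
            contig = rec.reference_name
            if contig not in known:
                raise ValueError(f"alignment to unknown contig {contig!r}")
            if rec.is_reverse:
                strand, p5 = "-", rec.reference_end - 1
            else:
                strand, p5 = "+", rec.reference_start
            if contig == JUNCTION_NAME:
                p5 = reference.lift_junction(p5)
                contig = reference.chrm_name
            alns.append(ReadAlignment(rec.query_name, contig, strand, p5, rec.mapping_quality, "external"))
    return alns, n_skipped


def reconcile_dual(
    linear: list[ReadAlignment],
    junction: list[ReadAlignment],
    reference: MaskedReference,
) -> list[ReadAlignment]:
    """Per read, keep the placement with the higher MAPQ (tie -> linear),
    lifting junction-contig coordinates into the mitochondrial frame."""
    by_linear = {a.read_id: a for a in linear}
    by_junction = {a.read_id: a for a in junction}
    out: list[ReadAlignment] = []
    for rid in sorted(set(by_linear) | set(by_junction)):
        lin, jun = by_linear.get(rid), by_junction.get(rid)
        if lin is not None and (jun is None or lin.mapq >= jun.mapq):
            chosen = lin
        else:
            chosen = jun
        if chosen.contig == JUNCTION_NAME:
            chosen = ReadAlignment(
                chosen.read_id,
                reference.chrm_name,
                chosen.strand,
                reference.lift_junction(chosen.five_prime_pos),
                chosen.mapq,
                chosen.source,
            )
        out.append(chosen)
    return out


def write_alignments_tsv(path: str | Path, alignments: list[ReadAlignment]) -> None:
    """BED6-like table of reconciled 5' ends."""
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tread_id\tmapq\tstrand\n")
        for a in alignments:
            fh.write(f"{a.contig}\t{a.five_prime_pos}\t{a.five_prime_pos + 1}\t{a.read_id}\t{a.mapq}\t{a.strand}\n")
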