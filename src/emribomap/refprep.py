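"""Masked dual-reference construction for circular-genome read mapping.

Reads from a circular mitochondrial genome face two mapping hazards:

* NUMTs — near-identical nuclear copies of mtDNA sequence — attract
  mitochondrial reads into multi-mapping. High-identity NUMT segments
  (local alignment score > 100, identity > 95%) are found with blastn and
  N-masked in the nuclear contigs.
* the artificial linearization origin — reads spanning it cannot map on
  the linear contig. A second reference version carries a circularization
  junction contig (the last `flank` bases concatenated to the first
  `flank` bases) with the corresponding flanks N-masked on the linear
  copy, so every read has exactly one valid placement per version.

A k-mer mappability track (exact single-copy k-mers over both strands)
supports composition-corrected incorporation rates downstream.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .genome import CircularGenome, revcomp
from .simulate import write_fasta

Interval = tuple[int, int]

JUNCTION_NAME = "chrM_junction"


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of 0-based half-open intervals, sorted and disjoint."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def mask_intervals(sequence: str, intervals: list[Interval]) -> str:
    """Replace the given intervals with N. Length-preserving, idempotent."""
    seq = list(sequence)
    for s, e in intervals:
        if s < 0 or e > len(seq) or s > e:
            raise ValueError(f"interval ({s},{e}) out of bounds for length {len(seq)}")
        seq[s:e] = "N" * (e - s)
    return "".join(seq)


def find_numt_segments(
    nuclear: dict[str, str],
    chrm: CircularGenome,
    min_score: float = 100,
    min_identity: float = 0.95,
) -> dict[str, list[Interval]]:
    """Locate NUMT segments: maximal local alignments of the mitochondrial
    sequence (both strands) against each nuclear contig with raw score
    strictly above ``min_score`` and identity strictly above
    ``min_identity`` (matches / aligned columns).

    Uses blastn with unit match scoring (+1/-2, gap open 5, extend 2), so
    the raw score threshold behaves as documented for high-identity
    inserts. Returns per-contig merged intervals on the nuclear contigs.
    """
    if not nuclear:
        return {}
    if shutil.which("blastn") is None:
        raise RuntimeError("blastn executable not found on PATH")
    hits: dict[str, list[Interval]] = {name: [] for name in nuclear}
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "chrM.fa"
        spath = Path(tmp) / "nuclear.fa"
        write_fasta(qpath, {chrm.name: chrm.sequence})
        write_fasta(spath, nuclear)
        cmd = [
            "blastn", "-task", "blastn",
            "-query", str(qpath), "-subject", str(spath),
            "-reward", "1", "-penalty", "-2",
            "-gapopen", "5", "-gapextend", "2",
            "-dust", "no", "-evalue", "1e-5",
            "-outfmt", "6 sseqid sstart send pident score",
        ]
        res = subprocess.run(cmd, capture_output=True, text=True, check=True)
        for line in res.stdout.splitlines():
            sseqid, sstart, send, pident, score = line.split("\t")
            if float(score) <= min_score or float(pident) / 100.0 <= min_identity:
                continue
            a, b = int(sstart), int(send)
            lo, hi = (a, b) if a <= b else (b, a)
            hits[sseqid].append((lo - 1, hi))  # 1-based inclusive -> 0-based half-open
    return {name: merge_intervals(iv) for name, iv in hits.items() if iv}


@dataclass
class MaskedReference:
    """Two reference versions sharing NUMT-masked nuclear contigs.

    * linear version: the linearized mitochondrial contig as-is;
    * junction version: the same contig with both `flank`-sized ends
      N-masked, plus a 2*flank junction contig whose position 0 maps to
      mitochondrial coordinate L - flank.
    """

    chrm_name: str
    chrm_seq: str
    flank: int
    nuclear: dict[str, str] = field(default_factory=dict)
    mask_intervals: dict[str, list[Interval]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.chrm_seq)

    @property
    def junction_offset(self) -> int:
        return self.length - self.flank

    @property
    def junction_seq(self) -> str:
        return self.chrm_seq[self.junction_offset :] + self.chrm_seq[: self.flank]

    @property
    def chrm_flank_masked(self) -> str:
        L, f = self.length, self.flank
        return mask_intervals(self.chrm_seq, [(0, f), (L - f, L)])

    def linear_contigs(self) -> dict[str, str]:
        return {self.chrm_name: self.chrm_seq, **self.nuclear}

    def junction_contigs(self) -> dict[str, str]:
        return {
            self.chrm_name: self.chrm_flank_masked,
            JUNCTION_NAME: self.junction_seq,
            **self.nuclear,
        }

    def lift_junction(self, j: int) -> int:
        """Junction-contig coordinate -> mitochondrial coordinate."""
        if not 0 <= j < 2 * self.flank:
            raise ValueError(f"junction position {j} outside [0, {2 * self.flank})")
        return (self.junction_offset + j) % self.length

    def delift(self, p: int) -> int:
        """Mitochondrial coordinate in the flank union -> junction-contig
        coordinate (inverse of :meth:`lift_junction`)."""
        L, f = self.length, self.flank
        if p >= L - f:
            return p - (L - f)
        if p < f:
            return p + f
        raise ValueError(f"position {p} not within the junction flanks")


def build_junction_reference(
    chrm: CircularGenome,
    flank: int = 200,
    nuclear: dict[str, str] | None = None,
    numt_min_score: float = 100,
    numt_min_identity: float = 0.95,
    mask_numts: bool = True,
) -> MaskedReference:
    """Assemble the dual reference: junction contig + flank-masked linear
    copy, with NUMT segments N-masked in any nuclear contigs supplied."""
    if not 0 < flank < chrm.length / 2:
        raise ValueError(f"flank must be in (0, L/2), got {flank} for L={chrm.length}")
    nuclear = dict(nuclear or {})
    masks: dict[str, list[Interval]] = {}
    if nuclear and mask_numts:
        masks = find_numt_segments(nuclear, chrm, numt_min_score, numt_min_identity)
        nuclear = {name: mask_intervals(seq, masks.get(name, [])) for name, seq in nuclear.items()}
    masks[chrm.name] = [(0, flank), (chrm.length - flank, chrm.length)]
    return MaskedReference(
        chrm_name=chrm.name,
        chrm_seq=chrm.sequence,
        flank=flank,
        nuclear=nuclear,
        mask_intervals=masks,
    )


def compute_mappability(contigs: dict[str, str], k: int = 100) -> dict[str, list[Interval]]:
    """Exact k-mer uniqueness track.

    A position p on contig c is mappable iff the k-mer starting there
    contains no N and occurs exactly once among all k-mers of all contigs
    *and their reverse complements*. A palindromic k-mer present once is
    counted on both strands and is therefore not unique.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for seq in contigs.values():
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                counts[s[i : i + k]] += 1
    track: dict[str, list[Interval]] = {}
    for name, seq in contigs.items():
        runs: list[Interval] = []
        start = None
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            ok = "N" not in kmer and counts[kmer] == 1
            if ok and start is None:
                start = i
            elif not ok and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(seq) - k + 1))
        track[name] = runs
    return track


def positions_in_track(track_intervals: list[Interval]) -> set[int]:
    return {p for s, e in track_intervals for p in range(s, e)}


def write_bed3(path: str | Path, per_contig: dict[str, list[Interval]]) -> None:
    with open(path, "w") as fh:
        for contig in sorted(per_contig):
            for s, e in per_contig[contig]:
                fh.write(f"{contig}\t{s}\t{e}\n")
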