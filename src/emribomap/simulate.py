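"""Synthetic emRiboSeq data with known ground truth.

RNase H2 nicks duplex DNA immediately 5' of an embedded ribonucleotide on
the ribo-containing strand. Second-strand sequencing reads therefore start
at the nick on the *opposite* strand: a ribo at position q on the minus
strand yields reads whose 5' end is at (q+1) mod L on the plus strand, and
a ribo at q on the plus strand yields reads whose 5' end is at (q-1) mod L
on the minus strand. The simulator emits reads with exactly this geometry
(the inverse of the caller's inference rule), so the whole pipeline can be
checked against truth by set equality.

Reads are error-free by default; the acceptance surface is geometric
recovery, not aligner robustness. A substitution-error knob exists for
stress tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import CircularGenome, as_dna, as_ribo, complement_base, revcomp

RIBO_BASES = ("A", "C", "G", "U")

#: Ion Proton 3' adapter used in the original libraries.
DEFAULT_ADAPTER = "ATCACCGACTGCCCATAGAGAGG"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """Raised when the requested truth cannot be realized on the genome."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults describe a liver-like condition: a ~16 kb circular genome of
    uniform composition carrying rA-dominant embedded ribonucleotides
    (80% rA / 5% rC / 10% rG / 5% rU) on both strands.
    """

    genome_length: int = 16_299
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_sites: int = 5_000
    target_proportions: tuple[float, float, float, float] = (0.80, 0.05, 0.10, 0.05)
    strand_bias: float = 0.5
    read_length: int = 50
    reads_per_site: int = 2
    noise_rate: float = 0.0
    adapter: str = DEFAULT_ADAPTER
    adapter_contamination_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0
    genome_name: str = "chrM"

    def __post_init__(self) -> None:
        for name in ("strand_bias", "noise_rate", "adapter_contamination_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("base_probs", "target_proportions"):
            p = getattr(self, name)
            if len(p) != 4 or any(x < 0 for x in p):
                raise ConfigError(f"{name} must be four non-negative values")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {sum(p)}")
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        if self.read_length >= self.genome_length:
            raise ConfigError("read_length must be smaller than the genome")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class TruthSite:
    """One embedded ribonucleotide: 0-based position, strand, and the ribo
    identity on its own strand (U where the DNA base is T)."""

    position: int
    strand: str  # '+' or '-'
    base: str  # A/C/G/U

    def key(self) -> tuple[int, str, str]:
        return (self.position, self.strand, self.base)


@dataclass
class SimTruth:
    """Ground truth for one simulation."""

    sites: list[TruthSite]
    noise_nicks: list[tuple[int, str]] = field(default_factory=list)
    seed: int = 0


@dataclass(frozen=True)
class ReadEmission:
    """Bookkeeping record for one emitted read: where its 5' end sits and
    which truth site (if any) produced it."""

    read_id: str
    strand: str
    five_prime_pos: int
    origin: str  # 'signal' or 'noise'
    site_index: int  # -1 for noise


@dataclass(frozen=True)
class SimReads:
    records: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    emissions: list[ReadEmission]


def generate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> CircularGenome:
    """Draw a circular genome of ``genome_length`` i.i.d. bases."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=config.genome_length, p=config.base_probs)
    seq = bases.tobytes().decode("ascii")
    return CircularGenome(config.genome_name, seq, circular=True)


def _eligible_positions(genome: CircularGenome, ribo_base: str) -> tuple[np.ndarray, np.ndarray]:
    """(plus_positions, minus_positions) whose underlying base matches a
    ribo identity: + strand needs the forward base itself, - strand needs
    its complement on the forward strand."""
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype="S1")
    dna = as_dna(ribo_base).encode("ascii")
    comp = complement_base(as_dna(ribo_base)).encode("ascii")
    plus = np.flatnonzero(arr == dna)
    minus = np.flatnonzero(arr == comp)
    return plus, minus


def embed_ribos(genome: CircularGenome, config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Sample ``n_sites`` embedded ribos without replacement over
    (position, strand) pairs, identities multinomial around
    ``target_proportions`` and positions uniform over eligible loci.
    """
    if config.n_sites > 2 * genome.length:
        raise ConfigError("n_sites exceeds the number of (position, strand) pairs")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    counts = rng.multinomial(config.n_sites, config.target_proportions)
    sites: list[TruthSite] = []
    for base, n_b in zip(RIBO_BASES, counts):
        if n_b == 0:
            continue
        plus, minus = _eligible_positions(genome, base)
        if n_b > len(plus) + len(minus):
            raise GenerationError(
                f"not enough eligible loci for ribo identity r{base}: "
                f"need {n_b}, have {len(plus) + len(minus)}"
            )
        n_plus = int(rng.binomial(n_b, config.strand_bias))
        # shift overflow to the other strand rather than fail
        n_plus = min(n_plus, len(plus))
        n_plus = max(n_plus, n_b - len(minus))
        chosen_plus = rng.choice(plus, size=n_plus, replace=False)
        chosen_minus = rng.choice(minus, size=n_b - n_plus, replace=False)
        sites.extend(TruthSite(int(p), "+", base) for p in chosen_plus)
        sites.extend(TruthSite(int(p), "-", base) for p in chosen_minus)
    sites.sort(key=lambda s: (s.position, s.strand))
    return SimTruth(sites=sites, seed=config.seed)


def _read_from_site(genome: CircularGenome, position: int, strand: str, read_length: int) -> tuple[str, int, str]:
    """Sequence, 5'-end position and strand of a read reporting a nick at
    (position, strand)."""
    L = genome.length
    if strand == "-":
        p5 = (position + 1) % L
        seq = genome.fetch(p5, read_length)
        return seq, p5, "+"
    p5 = (position - 1) % L
    start = (p5 - read_length + 1) % L
    seq = revcomp(genome.fetch(start, read_length))
    return seq, p5, "-"


def simulate_reads(
    genome: CircularGenome,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimReads:
    """Emit error-free emRiboSeq reads for every truth site, plus uniform
    background nicks and optional 3' adapter read-through.

    Noise nicks drawn here are appended to ``truth.noise_nicks``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    L = genome.length
    rl = config.read_length
    records: list[tuple[str, str, str]] = []
    emissions: list[ReadEmission] = []
    qual = "I" * rl

    def emit(seq: str, p5: int, strand: str, origin: str, site_index: int) -> None:
        rid = f"{origin}_{len(records)}"
        if config.adapter and config.adapter_contamination_rate > 0 and rng.random() < config.adapter_contamination_rate:
            lo, hi = 12, min(len(config.adapter), rl - 30)
            if hi >= lo:
                a = int(rng.integers(lo, hi + 1))
                seq = seq[: rl - a] + config.adapter[:a]
        if config.error_rate > 0:
            seq = _mutate(seq, config.error_rate, rng)
        records.append((rid, seq, qual[: len(seq)]))
        emissions.append(ReadEmission(rid, strand, p5, origin, site_index))

    for i, site in enumerate(truth.sites):
        seq, p5, strand = _read_from_site(genome, site.position, site.strand, rl)
        for _ in range(config.reads_per_site):
            emit(seq, p5, strand, "signal", i)

    n_signal = len(truth.sites) * config.reads_per_site
    if config.noise_rate > 0 and n_signal > 0:
        n_noise = int(round(config.noise_rate / (1.0 - config.noise_rate) * n_signal))
        for _ in range(n_noise):
            q = int(rng.integers(0, L))
            s = "+" if rng.random() < 0.5 else "-"
            truth.noise_nicks.append((q, s))
            seq, p5, strand = _read_from_site(genome, q, s, rl)
            emit(seq, p5, strand, "noise", -1)
    return SimReads(records=records, emissions=emissions)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def make_numt_contig(
    nuclear_length: int,
    genome: CircularGenome,
    fragment: tuple[int, int],
    identity: float,
    seed: int,
    name: str = "chr_nuc",
) -> tuple[CircularGenome, tuple[int, int], int]:
    """Build a random linear contig carrying one nuclear copy of a
    mitochondrial fragment (a NUMT) mutated to the requested identity.

    Returns the contig, the exact inserted interval (0-based half-open) and
    the number of substitutions introduced.
    """
    start, end = fragment
    if not (0 <= start < end <= genome.length):
        raise ConfigError("fragment must lie within [0, L)")
    if not 0.0 <= identity <= 1.0:
        raise ConfigError("identity must be in [0,1]")
    frag_len = end - start
    if frag_len > nuclear_length:
        raise ConfigError("fragment longer than the nuclear contig")
    rng = np.random.default_rng(seed)
    frag = list(genome.sequence[start:end])
    n_sub = int(round((1.0 - identity) * frag_len))
    for pos in rng.choice(frag_len, size=n_sub, replace=False):
        frag[pos] = rng.choice([b for b in "ACGT" if b != frag[pos]])
    background = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=nuclear_length - frag_len).tobytes().decode("ascii")
    insert_at = int(rng.integers(0, nuclear_length - frag_len + 1))
    seq = background[:insert_at] + "".join(frag) + background[insert_at:]
    contig = CircularGenome(name, seq, circular=False)
    return contig, (insert_at, insert_at + frag_len), n_sub


# ---------------------------------------------------------------------------
# file output


def write_fasta(path: str | Path, contigs: Sequence[CircularGenome] | dict[str, str], width: int = 70) -> None:
    """Write contigs to FASTA (accepts CircularGenome objects or a
    name -> sequence mapping)."""
    if isinstance(contigs, dict):
        items = list(contigs.items())
    else:
        items = [(c.name, c.sequence) for c in contigs]
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, reads: SimReads) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads.records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth_bed(path: str | Path, truth: SimTruth, chrom: str) -> None:
    """Truth sites as BED6: name = ribo base, score = 0."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for s in truth.sites:
            fh.write(f"{chrom}\t{s.position}\t{s.position + 1}\t{s.base}\t0\t{s.strand}\n")
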