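"""Composition-corrected summaries of embedded-ribonucleotide calls.

Raw per-base call proportions confound incorporation preference with the
genome's own base composition, so relative incorporation rates divide the
site counts by the number of times each base (or trinucleotide context)
occurs among uniquely mappable positions of the reference. Trinucleotide
context is taken on the ribo-containing strand with the ribo central.
Window profiles use circularly wrapped rolling windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import RiboSite
from .genome import CircularGenome, as_ribo, revcomp
from .refprep import Interval, positions_in_track

RIBO_BASES = ("A", "C", "G", "U")
DNA_BASES = ("A", "C", "G", "T")
ALL_TRINUCS = ["".join(t) for t in product(DNA_BASES, repeat=3)]


@dataclass(frozen=True)
class ProportionVector:
    """Four base proportions (A, C, G, U) summing to 1; an all-zero vector
    is the explicit empty marker."""

    pA: float
    pC: float
    pG: float
    pU: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0):
            raise ValueError("proportions must be non-negative")
        total = float(vals.sum())
        if total != 0.0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1 (or all be 0), got {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pA, self.pC, self.pG, self.pU], dtype=float)

    @property
    def is_empty(self) -> bool:
        return float(self.as_array().sum()) == 0.0

    @classmethod
    def from_counts(cls, counts) -> "ProportionVector":
        arr = np.asarray(counts, dtype=float)
        total = arr.sum()
        if total == 0:
            return cls(0.0, 0.0, 0.0, 0.0)
        arr = arr / total
        return cls(*arr)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(RIBO_BASES, self.as_array()))


EMPTY_PROPORTIONS = ProportionVector(0.0, 0.0, 0.0, 0.0)


@dataclass
class ProportionSummary:
    pooled: ProportionVector
    counts: dict[str, int]  # per ribo base, pooled
    per_strand_counts: dict[str, dict[str, int]]  # strand -> base -> count
    per_strand: dict[str, ProportionVector]
    n: int


def count_proportions(sites: list[RiboSite]) -> ProportionSummary:
    """Identity proportions of called sites, pooled and per strand."""
    per_strand_counts = {s: {b: 0 for b in RIBO_BASES} for s in "+-"}
    for site in sites:
        per_strand_counts[site.strand][site.base] += 1
    counts = {b: per_strand_counts["+"][b] + per_strand_counts["-"][b] for b in RIBO_BASES}
    return ProportionSummary(
        pooled=ProportionVector.from_counts([counts[b] for b in RIBO_BASES]),
        counts=counts,
        per_strand_counts=per_strand_counts,
        per_strand={
            s: ProportionVector.from_counts([per_strand_counts[s][b] for b in RIBO_BASES])
            for s in "+-"
        },
        n=len(sites),
    )


def site_context(site: RiboSite, genome: CircularGenome) -> str:
    """Trinucleotide context on the ribo-containing strand (ribo central,
    U written as T); circular wrap at the origin."""
    L = genome.length
    fwd = genome.fetch((site.position - 1) % L, 3)
    return fwd if site.strand == "+" else revcomp(fwd)


def tri_context(sites: list[RiboSite], genome: CircularGenome) -> tuple[pd.DataFrame, int]:
    """Per-site 3-mer contexts tabulated by strand.

    Returns (table indexed by context with '+'/'-'/'total' columns,
    n_excluded_for_N). The central context base always equals the site's
    ribo identity (U <-> T)."""
    counts = {s: {} for s in "+-"}
    n_excluded = 0
    for site in sites:
        ctx = site_context(site, genome)
        if "N" in ctx:
            n_excluded += 1
            continue
        assert as_ribo(ctx[1]) == site.base, f"context {ctx} inconsistent with site base {site.base}"
        counts[site.strand][ctx] = counts[site.strand].get(ctx, 0) + 1
    contexts = sorted(set(counts["+"]) | set(counts["-"]))
    df = pd.DataFrame(
        {
            "+": [counts["+"].get(c, 0) for c in contexts],
            "-": [counts["-"].get(c, 0) for c in contexts],
        },
        index=pd.Index(contexts, name="context"),
    )
    df["total"] = df["+"] + df["-"]
    return df, n_excluded


@dataclass
class CompositionTable:
    """Mono- and trinucleotide composition of (mappable) reference
    positions, per strand. The minus-strand composition is the complement
    (reverse complement for 3-mers) of the forward sequence."""

    genome_name: str
    genome_length: int
    base_counts: dict[str, dict[str, int]]  # strand -> DNA base -> count
    trinuc_counts: dict[str, dict[str, int]]  # strand -> 3-mer -> count
    n_positions: int  # mappable positions per strand

    def pooled_base_counts(self) -> dict[str, int]:
        return {b: self.base_counts["+"][b] + self.base_counts["-"][b] for b in DNA_BASES}

    def forward_proportions(self) -> ProportionVector:
        """Base composition of the forward (light) strand as ribo-identity
        proportions (T counted as U)."""
        c = self.base_counts["+"]
        return ProportionVector.from_counts([c["A"], c["C"], c["G"], c["T"]])


def composition_table(
    genome: CircularGenome,
    mappable: list[Interval] | None = None,
) -> CompositionTable:
    """Composition over mappable forward positions (all positions when
    ``mappable`` is None, for fully unique synthetic references).

    For each forward position p the plus-strand base is forward[p] with
    context forward[p-1..p+1]; the minus-strand base/context are their
    complements. Positions whose base or context contains N are skipped
    from the respective table."""
    if mappable is None:
        positions = range(genome.length)
        n_positions = genome.length
    else:
        pos_set = sorted(positions_in_track(mappable))
        positions = pos_set
        n_positions = len(pos_set)
    base_counts = {s: {b: 0 for b in DNA_BASES} for s in "+-"}
    trinuc_counts = {s: {} for s in "+-"}
    for p in positions:
        fwd = genome.base(p)
        if fwd == "N":
            n_positions -= 1
            continue
        base_counts["+"][fwd] += 1
        base_counts["-"][revcomp(fwd)] += 1
        ctx = genome.fetch((p - 1) % genome.length, 3) if genome.circular else None
        if ctx is None and 1 <= p <= genome.length - 2:
            ctx = genome.sequence[p - 1 : p + 2]
        if ctx and "N" not in ctx:
            trinuc_counts["+"][ctx] = trinuc_counts["+"].get(ctx, 0) + 1
            rc = revcomp(ctx)
            trinuc_counts["-"][rc] = trinuc_counts["-"].get(rc, 0) + 1
    return CompositionTable(
        genome_name=genome.name,
        genome_length=genome.length,
        base_counts=base_counts,
        trinuc_counts=trinuc_counts,
        n_positions=n_positions,
    )


def normalize_rates(
    sites: list[RiboSite],
    composition: CompositionTable,
    genome: CircularGenome,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Composition-corrected incorporation rates.

    rate(x) = sites with identity (or context) x / occurrences of x among
    the composition's positions, per strand and pooled. A class absent
    from the mappable reference yields a missing value, never 0.

    Returns (per-base table, per-3-mer table).
    """
    if composition.genome_name != genome.name or composition.genome_length != genome.length:
        raise ValueError("composition table does not match the site reference")
    site_base = {s: {b: 0 for b in RIBO_BASES} for s in "+-"}
    site_ctx = {s: {} for s in "+-"}
    for site in sites:
        site_base[site.strand][site.base] += 1
        ctx = site_context(site, genome)
        if "N" not in ctx:
            site_ctx[site.strand][ctx] = site_ctx[site.strand].get(ctx, 0) + 1

    rows = []
    for rb in RIBO_BASES:
        db = "T" if rb == "U" else rb
        row = {"base": rb}
        for strand in "+-":
            n_sites = site_base[strand][rb]
            n_ref = composition.base_counts[strand][db]
            row[f"sites_{strand}"] = n_sites
            row[f"ref_{strand}"] = n_ref
            row[f"rate_{strand}"] = n_sites / n_ref if n_ref else math.nan
        tot_sites = row["sites_+"] + row["sites_-"]
        tot_ref = row["ref_+"] + row["ref_-"]
        row["rate_pooled"] = tot_sites / tot_ref if tot_ref else math.nan
        rows.append(row)
    base_df = pd.DataFrame(rows).set_index("base")

    ctx_rows = []
    seen = sorted(
        set(site_ctx["+"]) | set(site_ctx["-"])
        | set(composition.trinuc_counts["+"]) | set(composition.trinuc_counts["-"])
    )
    for ctx in seen:
        row = {"context": ctx}
        for strand in "+-":
            n_sites = site_ctx[strand].get(ctx, 0)
            n_ref = composition.trinuc_counts[strand].get(ctx, 0)
            row[f"sites_{strand}"] = n_sites
            row[f"ref_{strand}"] = n_ref
            row[f"rate_{strand}"] = n_sites / n_ref if n_ref else math.nan
        tot_sites = row["sites_+"] + row["sites_-"]
        tot_ref = row["ref_+"] + row["ref_-"]
        row["rate_pooled"] = tot_sites / tot_ref if tot_ref else math.nan
        ctx_rows.append(row)
    ctx_df = pd.DataFrame(ctx_rows).set_index("context") if ctx_rows else pd.DataFrame()
    return base_df, ctx_df


def window_profile(
    sites: list[RiboSite],
    genome_length: int,
    window_size: int = 200,
    step: int = 20,
    mappable: list[Interval] | None = None,
) -> pd.DataFrame:
    """Circular rolling-window site counts.

    Windows start at 0, step, 2*step, ... and wrap the origin. Columns:
    per-strand per-base counts, totals, and rate per (mappable) base.
    With step == window_size the windows tile the circle and counts sum to
    the total number of sites."""
    if window_size > genome_length:
        raise ValueError("window_size must not exceed the genome length")
    L = genome_length
    starts = np.arange(0, L, step)
    per_pos = {s: {b: np.zeros(L, dtype=np.int64) for b in RIBO_BASES} for s in "+-"}
    for site in sites:
        per_pos[site.strand][site.base][site.position] += 1
    mappable_mask = np.zeros(L, dtype=np.int64)
    if mappable is None:
        mappable_mask[:] = 1
    else:
        for s, e in mappable:
            mappable_mask[s:e] = 1

    def circ_window_sum(arr: np.ndarray) -> np.ndarray:
        ext = np.concatenate([arr, arr[: window_size - 1]]) if window_size > 1 else arr
        csum = np.concatenate([[0], np.cumsum(ext)])
        return csum[starts + window_size] - csum[starts]

    data = {"start": starts}
    total = np.zeros(len(starts), dtype=np.int64)
    for strand in "+-":
        for base in RIBO_BASES:
            col = circ_window_sum(per_pos[strand][base])
            data[f"{base}_{strand}"] = col
            total += col
    data["total"] = total
    mappable_bases = circ_window_sum(mappable_mask)
    data["mappable_bases"] = mappable_bases
    with np.errstate(divide="ignore", invalid="ignore"):
        data["rate"] = np.where(mappable_bases > 0, total / np.maximum(mappable_bases, 1), np.nan)
    return pd.DataFrame(data)


def write_proportions_tsv(path: str | Path, summary: ProportionSummary) -> None:
    rows = []
    for b in RIBO_BASES:
        rows.append(
            {
                "base": f"r{b}",
                "count": summary.counts[b],
                "proportion": summary.pooled.as_dict()[b],
                "count_plus": summary.per_strand_counts["+"][b],
                "count_minus": summary.per_strand_counts["-"][b],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_window_bedgraph(path: str | Path, profile: pd.DataFrame, chrom: str) -> None:
    with open(path, "w") as fh:
        for _, row in profile.iterrows():
            fh.write(f"{chrom}\t{int(row['start'])}\t{int(row['start']) + 1}\t{row['total']}\n")
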