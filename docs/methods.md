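# Methods

## The inference rule and its geometry

RNase H2 cleaves the ribo-containing strand on the 5′ side of a single
embedded ribonucleotide; second-strand synthesis and sequencing start at
the nick on the opposite strand. The caller therefore inverts the read
geometry: a plus-strand read with 5′ end p calls a site at (p−1) mod L
on the minus strand (base = complement of the forward base, T reported
as U); a minus-strand read with 5′ end p calls (p+1) mod L on the plus
strand (base = forward base, T→U). "Upstream" is interpreted in the
read's own orientation — one base 5′ of the read's 5′ end, then
strand-flipped — which is the only reading consistent with cleavage 5′
of the ribo and nick-initiated second-strand reads. The simulator
implements the exact inverse map, so with zero noise the pipeline's call
set must equal the simulated truth set *exactly*, and the test suite
asserts set equality rather than a correlation.

rU and rT (ribo-U opposite A, and rTMP) are reported as a single class
"U": after RNase H2 cleavage the two are not distinguishable by read
geometry, only by the underlying reference base, which is the same.

## Reference preparation

**NUMT masking.** Nuclear copies of mitochondrial sequence are found by
local alignment of the mitochondrial contig (both strands) against each
nuclear contig using `blastn` with unit scoring (match +1, mismatch −2,
gap open 5, gap extend 2, dust off). Segments with raw score > 100 and
identity > 95% are N-masked. With this scoring a 500-bp insert at 96%
identity scores ≈ 440 and passes both thresholds, while a 90% insert is
excluded by the identity filter — the masking behaviour the thresholds
are designed to produce, which the tests verify from simulated inserts
of known identity. The score/identity thresholds are parameters of
`find_numt_segments`; the scoring scheme is a documented package choice,
since a threshold on a "score" is meaningless without one.

**Junction contig.** The circular genome is linearized from a fixed
origin. The junction contig concatenates the last `flank` (default 200)
bases with the first `flank` bases; in the junction reference version
the corresponding flanks of the linear copy are N-masked, so each read
has at most one valid placement per version. Junction coordinate j lifts
to (L − flank + j) mod L; the lift is bijective over the flank union and
the tests check this exhaustively. Reads are aligned to both versions
and reconciled per read by MAPQ; ties prefer the linear version (a
determinism choice — both placements describe the same locus, and the
linear one needs no lift).

**Mappability.** A position is mappable iff the k-mer starting there
(default k = 100, configurable) contains no N and occurs exactly once
among all k-mers of all contigs *and their reverse complements*; a
palindromic k-mer present once is counted on both strands and is
therefore never unique. This is an exact, portable stand-in for
precomputed alignability tracks, applicable to synthetic genomes; it is
computed by hashing and verified against a brute-force string recount in
the tests. Random synthetic genomes are essentially fully unique at the
default read length, so the pipeline's default is to normalize over the
whole genome, with mappability restriction available as a flag
(`RunConfig.use_mappability`).

## Read processing

**Adapter clipping** removes the longest read suffix exactly matching a
prefix of the 3′ adapter with ≥ 12 bases of overlap, and discards reads
shorter than 30 nt after clipping. Matching is exact: the simulator
introduces no adapter errors, so the overlap/length contract is
reproduced without an error model.

**Internal aligner.** Synthetic reads are error-free, so placement is
exact-substring search (seeded on the first 16 bases, verified in full)
over both strands of every contig. Unique placements get MAPQ 60,
multiple placements MAPQ 0 — only the downstream ≥ 30 threshold matters.
Real libraries enter via SAM/BAM ingest (`pysam`), which takes the 5′
end as the first *aligned* base (reference start for plus-strand reads,
rightmost aligned base for minus-strand reads) and lifts junction-contig
records; aligner choice stays external.

## Statistics

Per-base proportions are reported pooled and per strand; the empty case
is an explicit all-zero marker, never NaN. Trinucleotide context is the
3-mer on the ribo-containing strand with the ribo central (reverse
complement of the forward 3-mer for minus-strand sites), wrapping the
origin. Incorporation rates divide site counts by the occurrence count
of the base/3-mer among (mappable) reference positions, per strand and
pooled; a class absent from the reference yields a missing value, not
zero. Window profiles use circularly wrapped rolling windows (default
200 nt window, 20 nt step — package defaults, as no canonical values
exist); with step = window size the windows tile the circle and counts
are conserved, which is tested. Genome base composition for the
expectation models uses the forward (linearized) strand by default; the
composition table also carries both-strand counts.

## Expectation models

The four modes (composition / ratio / df / composite) weight the genome
base frequencies f_b by the rNTP:dNTP ratio and/or the inverse
polymerase discrimination factor and renormalize. Algebraic identities —
reduction to f_b under equal pools, composite = ratio at constant DF,
composite = df at constant ratio, invariance to common rescaling of all
concentrations — are tested to 1e−12. Pool concentrations and DF values
are runtime inputs (TSV), never constants; the shipped
`pools_synthetic_liver.tsv` is a synthetic illustrative table whose
composite expectation is rA-dominant with rG second, the qualitative
solid-tissue pattern. Model comparison reports total-variation distance,
a chi-square statistic at the observed sample size (flagged undefined
when the expectation has exact zeros opposite nonzero counts), a
multinomial-bootstrap CI on the distance, and bootstrap mode-ranking
frequencies.

## Synthetic data: what it does and does not emulate

The generator draws an i.i.d. circular genome, embeds ribos without
replacement over (position, strand) pairs — one ribo per strand per
locus, which keeps truth bookkeeping exact — with identities multinomial
around target proportions (defaults are the liver-like 0.80/0.05/0.10/
0.05) and positions uniform over eligible loci, then emits error-free
reads by the inverse inference rule, plus uniform background nicks
(`noise_rate`) and 3′ adapter read-through (`adapter_contamination_rate`,
adapter portion 12–23 nt so clipped reads stay mappable). Per-site read
multiplicity is a constant knob (`reads_per_site`, default 2); real
libraries have unknown, overdispersed multiplicity. Not modeled: PCR
duplicates, GC bias, fragment-size distributions, sequencing errors
(knob exists, default 0), or realistic mtDNA base composition (the
default genome is uniform). Passing tests therefore demonstrate
geometric and statistical correctness of the pipeline, not robustness
to real-library artifacts — that is what the external-aligner SAM ingest
path is for.

Because sites are sampled without replacement, a genome of length L
hosts at most 2L sites and far fewer of any one identity; large-n
proportion-recovery runs therefore use a longer random circle (163 kb
for n = 50,000 at 80% rA) so that eligible loci are not exhausted, while
exact round-trip runs keep the mitochondrial L = 16,299.

## Numerical and design choices

* All randomness flows through `numpy` Generators seeded from a single
  integer (`SeedSequence.spawn` per stage); identical config + seed
  gives byte-identical outputs, asserted by checksum in the tests.
* MAPQ reconciliation assumes the two reference versions share a MAPQ
  scale (true for the internal aligner and for one external aligner run
  on both versions).
* Reads calling the same (position, strand) are kept as separate
  records; deduplication of identical 5′ ends is deliberately not
  applied (a documented knob for future real-data use).
* Problem sizes in the acceptance script (10,000-site round trip,
  50,000-site proportion recovery, 500-bp NUMT inserts, 400-position
  junction sweep) were chosen to make binomial/bootstrap tolerances
  tight at interactive runtimes on a single CPU.

## Known limitations

* The internal aligner tolerates no mismatches; real reads must be
  aligned externally and ingested as SAM/BAM.
* NUMT detection requires the `blastn` executable on PATH.
* Mappability is single-k exact uniqueness, not an alignability model
  with mismatches.
* The expectation models treat polymerase discrimination as a scalar
  per base; no kinetic modeling, and DF values are not fit from data.
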