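"""Read processing: adapter trimming, exact placement, SAM ingest, and
dual-reference MAPQ reconciliation."""

from pathlib import Path

import pytest

from emribomap import (
    CircularGenome,
    SimConfig,
    align_exact,
    build_junction_reference,
    generate_genome,
    ingest_sam,
    make_numt_contig,
    reconcile_dual,
    trim_adapter,
    trim_reads,
)
from emribomap.genome import revcomp
from emribomap.reads import ReadAlignment
from emribomap.refprep import JUNCTION_NAME
from emribomap.simulate import DEFAULT_ADAPTER

ADAPTER = DEFAULT_ADAPTER


def _genomic(n, seed=77):
    return generate_genome(SimConfig(genome_length=max(n, 64), seed=seed)).sequence[:n]


class TestTrimAdapter:
    def test_14nt_adapter_suffix_trimmed(self):
        read = _genomic(36) + ADAPTER[:14]
        seq, qual = trim_adapter(read, "I" * 50, ADAPTER)
        assert len(seq) == 36 and len(qual) == 36
        assert seq == read[:36]

    def test_trimmed_below_min_length_discarded(self):
        read = _genomic(25) + ADAPTER[:15]
        assert trim_adapter(read, "I" * 40, ADAPTER) is None

    def test_short_overlap_left_untouched(self):
        read = _genomic(42) + ADAPTER[:8]
        seq, _ = trim_adapter(read, "I" * 50, ADAPTER)
        assert seq == read

    @pytest.mark.parametrize(
        "overlap,expect",
        [(11, "untouched"), (12, "trimmed"), (20, "trimmed"), (21, "discarded"), (23, "discarded")],
    )
    def test_retain_trim_discard_matrix(self, overlap, expect):
        """Boundary matrix for overlap=12 / minimum-length=30 on 50-nt
        reads: <12 adapter bases leave the read untouched, >=12 trim, and
        trims leaving <30 nt discard the read."""
        read = _genomic(50 - overlap) + ADAPTER[:overlap]
        assert len(read) == 50
        res = trim_adapter(read, "I" * 50, ADAPTER, min_overlap=12, min_length=30)
        if expect == "discarded":
            assert res is None
        elif expect == "untouched":
            assert res[0] == read
        else:
            assert res[0] == read[: 50 - overlap]

    def test_batch_counts(self):
        records = [
            ("keep", _genomic(50), "I" * 50),
            ("clip", _genomic(38) + ADAPTER[:12], "I" * 50),
            ("drop", _genomic(20) + ADAPTER[:20], "I" * 40),
        ]
        kept, st = trim_reads(records, ADAPTER)
        assert (st.n_input, st.n_trimmed, st.n_discarded, st.n_untouched) == (3, 1, 1, 1)
        assert [r[0] for r in kept] == ["keep", "clip"]

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT" * 10, "I" * 40, "")


@pytest.fixture(scope="module")
def genome():
    return generate_genome(SimConfig(genome_length=6_000, seed=31))


@pytest.fixture(scope="module")
def reference(genome):
    return build_junction_reference(genome, flank=200)


class TestAlignExact:
    def test_unique_read_gets_mapq60(self, genome, reference):
        read = genome.sequence[1_000:1_050]
        per, _ = align_exact([("r1", read, "I" * 50)], reference)
        (a,) = per["linear"]
        assert (a.contig, a.strand, a.five_prime_pos, a.mapq) == (genome.name, "+", 1_000, 60)

    def test_minus_strand_five_prime_is_rightmost(self, genome, reference):
        read = revcomp(genome.sequence[2_000:2_050])
        per, _ = align_exact([("r1", read, "I" * 50)], reference)
        (a,) = per["linear"]
        assert (a.strand, a.five_prime_pos) == ("-", 2_049)

    def test_unmasked_numt_copy_multimaps_until_masked(self, genome):
        numt, _, _ = make_numt_contig(20_000, genome, (1_000, 1_500), identity=1.0, seed=3)
        read = genome.sequence[1_200:1_250]
        unmasked = build_junction_reference(genome, flank=200, nuclear={numt.name: numt.sequence}, mask_numts=False)
        per, _ = align_exact([("r1", read, "I" * 50)], unmasked)
        assert per["linear"][0].mapq == 0
        masked = build_junction_reference(genome, flank=200, nuclear={numt.name: numt.sequence}, mask_numts=True)
        per, _ = align_exact([("r1", read, "I" * 50)], masked)
        assert per["linear"][0].mapq == 60

    def test_origin_spanning_read_only_on_junction_contig(self, genome, reference):
        read = genome.sequence[-25:] + genome.sequence[:25]
        per, stats = align_exact([("r1", read, "I" * 50)], reference)
        assert per["linear"] == []
        assert stats["linear"].n_unplaced == 1
        (a,) = per["junction"]
        assert a.contig == JUNCTION_NAME and a.five_prime_pos == 175 and a.mapq == 60


class TestReconcileDual:
    def test_higher_mapq_wins(self, reference):
        lin = [ReadAlignment("r", "chrM", "+", 100, 42, "linear")]
        jun = [ReadAlignment("r", JUNCTION_NAME, "+", 10, 11, "junction")]
        (kept,) = reconcile_dual(lin, jun, reference)
        assert kept.five_prime_pos == 100 and kept.source == "linear"

    def test_tie_keeps_linear(self, reference):
        lin = [ReadAlignment("r", "chrM", "+", 100, 60, "linear")]
        jun = [ReadAlignment("r", JUNCTION_NAME, "+", 10, 60, "junction")]
        (kept,) = reconcile_dual(lin, jun, reference)
        assert kept.source == "linear"

    def test_junction_only_read_lifted_mod_L(self, genome, reference):
        jun = [ReadAlignment("r", JUNCTION_NAME, "+", 175, 60, "junction")]
        (kept,) = reconcile_dual([], jun, reference)
        assert kept.contig == genome.name
        assert kept.five_prime_pos == (genome.length - 200 + 175) % genome.length

    def test_no_read_appears_twice(self, reference):
        lin = [ReadAlignment(f"r{i}", "chrM", "+", i, 60, "linear") for i in range(5)]
        jun = [ReadAlignment(f"r{i}", JUNCTION_NAME, "+", i, 60, "junction") for i in range(3, 8)]
        out = reconcile_dual(lin, jun, reference)
        ids = [a.read_id for a in out]
        assert len(ids) == len(set(ids)) == 8


class TestIngestSam:
    def _write_sam(self, tmp_path: Path, genome, lines: list[str]) -> Path:
        header = [
            "@HD\tVN:1.6\tSO:unsorted",
            f"@SQ\tSN:{genome.name}\tLN:{genome.length}",
            f"@SQ\tSN:{JUNCTION_NAME}\tLN:400",
        ]
        path = tmp_path / "toy.sam"
        path.write_text("\n".join(header + lines) + "\n")
        return path

    def test_plus_strand_pos_is_zero_based(self, tmp_path, genome, reference):
        seq = genome.sequence[100:140]
        sam = self._write_sam(tmp_path, genome, [f"r1\t0\t{genome.name}\t101\t60\t40M\t*\t0\t0\t{seq}\t*"])
        alns, _ = ingest_sam(sam, reference)
        assert alns[0].five_prime_pos == 100 and alns[0].strand == "+"

    def test_minus_strand_five_prime_is_rightmost(self, tmp_path, genome, reference):
        seq = revcomp(genome.sequence[200:250])
        sam = self._write_sam(tmp_path, genome, [f"r1\t16\t{genome.name}\t201\t60\t50M\t*\t0\t0\t{seq}\t*"])
        alns, _ = ingest_sam(sam, reference)
        assert alns[0].five_prime_pos == 249 and alns[0].strand == "-"

    def test_soft_clip_five_prime_is_first_aligned_base(self, tmp_path, genome, reference):
        seq = "ACGTA" + genome.sequence[300:335]
        sam = self._write_sam(tmp_path, genome, [f"r1\t0\t{genome.name}\t301\t60\t5S35M\t*\t0\t0\t{seq}\t*"])
        alns, _ = ingest_sam(sam, reference)
        assert alns[0].five_prime_pos == 300

    def test_junction_record_lifted(self, tmp_path, genome, reference):
        sam = self._write_sam(tmp_path, genome, [f"r1\t0\t{JUNCTION_NAME}\t51\t60\t40M\t*\t0\t0\t{'A' * 40}\t*"])
        alns, _ = ingest_sam(sam, reference)
        assert alns[0].contig == genome.name
        assert alns[0].five_prime_pos == (genome.length - 200 + 50) % genome.length

    def test_unmapped_skipped_and_counted(self, tmp_path, genome, reference):
        sam = self._write_sam(tmp_path, genome, ["r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*"])
        alns, n_skipped = ingest_sam(sam, reference)
        assert alns == [] and n_skipped == 1

    def test_unknown_contig_errors(self, tmp_path, genome, reference):
        sam = self._write_sam(tmp_path, genome, ["r1\t0\tchrX\t10\t60\t4M\t*\t0\t0\tACGT\t*"])
        # header lacks chrX, so pysam itself rejects the record; add it
        path = tmp_path / "toy2.sam"
        path.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chrX\tLN:1000\n"
            "r1\t0\tchrX\t10\t60\t4M\t*\t0\t0\tACGT\t*\n"
        )
        with pytest.raises(ValueError, match="chrX"):
            ingest_sam(path, reference)
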