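"""End-to-end orchestration: simulate -> prep-ref -> trim -> align ->
reconcile -> call -> stats -> model, with a machine-readable manifest.

Each stage writes its outputs through file boundaries so any single stage
can be replaced (e.g. external aligner SAM instead of the internal exact
aligner). Re-running with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calls import call_sites, filter_mapq, write_sites_bed
from .genome import CircularGenome
from .model import MODEL_MODES, PoolTable, compare_proportions, expected_proportions, write_model_report
from .reads import align_exact, reconcile_dual, trim_reads, write_alignments_tsv
from .refprep import build_junction_reference, compute_mappability, write_bed3
from .simulate import (
    SimConfig,
    embed_ribos,
    generate_genome,
    simulate_reads,
    write_fasta,
    write_fastq,
    write_truth_bed,
)
from .stats import (
    composition_table,
    count_proportions,
    normalize_rates,
    window_profile,
    write_proportions_tsv,
)


class StageError(RuntimeError):
    """A named pipeline stage failed."""


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    mapq_threshold: int = 30
    min_overlap: int = 12
    min_length: int = 30
    flank: int = 200
    mappability_k: int = 100
    numt_min_score: float = 100.0
    numt_min_identity: float = 0.95
    window_size: int = 200
    window_step: int = 20
    use_mappability: bool = False  # synthetic references are fully unique
    pools_path: str | None = None
    outdir: str = "emribomap_run"
    seed: int = 0


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "sim"},
            "sim": dataclasses.asdict(config.sim),
        },
        "counts": {},
    }
    counts = manifest["counts"]

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001
                manifest["failed_stage"] = name
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    sim = dataclasses.replace(config.sim, seed=config.seed)
    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_sites, rng_reads = (np.random.default_rng(s) for s in ss.spawn(3))

    def _simulate():
        genome = generate_genome(sim, rng_genome)
        truth = embed_ribos(genome, sim, rng_sites)
        reads = simulate_reads(genome, truth, sim, rng_reads)
        write_fasta(out / "genome.fa", [genome])
        write_fastq(out / "reads.fastq", reads)
        write_truth_bed(out / "truth.bed", truth, genome.name)
        (out / "sim_config.json").write_text(sim.to_json())
        return genome, truth, reads

    genome, truth, reads = stage("simulate")(_simulate)
    counts["truth_sites"] = len(truth.sites)
    counts["reads"] = len(reads.records)

    def _prep():
        ref = build_junction_reference(genome, flank=config.flank)
        write_fasta(out / "ref_linear.fa", ref.linear_contigs())
        write_fasta(out / "ref_junction.fa", ref.junction_contigs())
        write_bed3(out / "mask.bed", ref.mask_intervals)
        return ref

    reference = stage("prep-ref")(_prep)

    def _trim():
        kept, st = trim_reads(reads.records, sim.adapter, config.min_overlap, config.min_length)
        return kept, st

    trimmed, trim_stats = stage("trim")(_trim)
    counts["trimmed_kept"] = len(trimmed)
    counts["trim_discarded"] = trim_stats.n_discarded
    counts["trim_clipped"] = trim_stats.n_trimmed

    def _align():
        per_version, align_stats = align_exact(trimmed, reference)
        reconciled = reconcile_dual(per_version["linear"], per_version["junction"], reference)
        write_alignments_tsv(out / "alignments.tsv", reconciled)
        return reconciled, align_stats

    reconciled, align_stats = stage("align")(_align)
    counts["reconciled"] = len(reconciled)
    counts["unplaced_linear"] = align_stats["linear"].n_unplaced
    counts["unplaced_junction"] = align_stats["junction"].n_unplaced

    def _call():
        passing, n_removed = filter_mapq(reconciled, config.mapq_threshold)
        sites, n_dropped = call_sites(passing, genome)
        write_sites_bed(out / "sites.bed", sites, genome.name)
        return sites, n_removed, n_dropped

    sites, n_mapq_removed, n_dropped_n = stage("call")(_call)
    counts["mapq_filtered_out"] = n_mapq_removed
    counts["called_sites"] = len(sites)
    counts["dropped_on_N"] = n_dropped_n
    if not sites:
        manifest["warning"] = "no sites called; check MAPQ threshold and inputs"

    def _stats():
        mappable = None
        if config.use_mappability:
            track = compute_mappability(reference.linear_contigs(), k=config.mappability_k)
            write_bed3(out / "mappability.bed", track)
            mappable = track.get(genome.name, [])
        comp = composition_table(genome, mappable)
        summary = count_proportions(sites)
        write_proportions_tsv(out / "proportions.tsv", summary)
        base_rates, ctx_rates = normalize_rates(sites, comp, genome)
        base_rates.to_csv(out / "rates_base.tsv", sep="\t")
        ctx_rates.to_csv(out / "rates_trinucleotide.tsv", sep="\t")
        profile = window_profile(sites, genome.length, config.window_size, config.window_step, mappable)
        profile.to_csv(out / "window_profile.tsv", sep="\t", index=False)
        return comp, summary

    comp, summary = stage("stats")(_stats)

    def _model():
        if config.pools_path is None or summary.n == 0:
            return None
        pools = PoolTable.from_tsv(config.pools_path)
        f = comp.forward_proportions()
        expectations = {m: expected_proportions(m, f, pools) for m in MODEL_MODES}
        obs_counts = [summary.counts[b] for b in "ACGU"]
        report = compare_proportions(
            obs_counts, expectations["composite"], alternatives=expectations, seed=config.seed
        )
        write_model_report(out / "model_report.tsv", summary.pooled, expectations, report)
        return report

    model_report = stage("model")(_model)
    if model_report is not None:
        manifest["model"] = {
            "tv_to_composite": model_report.tv,
            "mode_ranking": model_report.mode_ranking,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
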