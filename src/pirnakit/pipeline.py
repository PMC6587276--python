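"""End-to-end pipelines composing the analysis stages.

``run_signature_pipeline``: load -> contaminant depletion -> size
selection -> genome mapping at 0 mismatches (the RPM denominator and
uniqueness calls) -> TE mapping at up to 3 mismatches -> overlap
histogram, Z-score, ping-pong partners and 1U/10A biases -> density
profile -> piRNA-cluster composition.  All reports are tab-separated;
a JSON manifest records inputs, parameters and stage counts so a run is
reproducible from the manifest alone.

``run_insertion_pipeline``: junction-read and discordant-pair detection
-> candidate calling -> annotation -> TSV/BED reports plus manifest.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field

from . import __version__
from .io import (
    IntervalSet,
    ReadSet,
    ReferenceSet,
    filter_exact_contaminant,
    load_fastq_pairs,
    load_intervals,
    load_reads,
    load_references,
)
from .insertions import (
    InsertSizePrior,
    JunctionParams,
    annotate_candidates,
    call_insertions,
    find_discordant_pairs,
    find_junction_reads,
    write_candidates_bed,
    write_candidates_tsv,
)
from .mapper import ReferenceIndex, best_placements, genome_unique_status, map_reads
from .signatures import (
    WINDOW_PRESETS,
    cluster_composition,
    density_profile,
    nucleotide_bias,
    overlap_histogram,
    signature_report,
)

logger = logging.getLogger("pirnakit")


@dataclass
class SignatureConfig:
    """Parameters of the signature pipeline."""

    pirna_min_len: int = 23
    pirna_max_len: int = 29
    library_min_len: int = 18
    library_max_len: int = 30
    max_mismatches_te: int = 3
    window_size: int | None = None  # None: look up WINDOW_PRESETS by TE name
    contaminant: str | None = None  # e.g. the 2S rRNA sequence
    counts_in_header: bool = False
    z_include_self: bool = False


@dataclass
class SignatureResult:
    report: object
    histogram: object
    profile: object
    composition: object | None
    normalization_total: int
    stage_counts: dict


def _window_for(te_name: str, cfg: SignatureConfig, te_length: int) -> int:
    if cfg.window_size is not None:
        return cfg.window_size
    if te_name in WINDOW_PRESETS:
        return WINDOW_PRESETS[te_name]
    # fall back to ~93 windows across the element, the preset density
    return max(1, math.ceil(te_length / 93))


def run_signature_pipeline(
    reads: ReadSet | str,
    te: ReferenceSet | str,
    genome: ReferenceSet | str | None = None,
    clusters: IntervalSet | str | None = None,
    cfg: SignatureConfig = SignatureConfig(),
    outdir: str | None = None,
) -> SignatureResult:
    """Run the full small-RNA signature analysis for one TE consensus."""
    if isinstance(reads, str):
        reads = load_reads(
            reads, cfg.library_min_len, cfg.library_max_len,
            counts_in_header=cfg.counts_in_header,
        )
    if isinstance(te, str):
        te = load_references(te)
    if isinstance(genome, str):
        genome = load_references(genome)
    if isinstance(clusters, str):
        clusters = load_intervals(clusters)
    te_names = te.names()
    if len(te_names) != 1:
        raise ValueError("signature pipeline expects exactly one TE consensus")
    te_name = te_names[0]
    te_length = len(te[te_name])

    stage_counts: dict[str, int] = {"loaded_total": reads.total_count}
    if cfg.contaminant:
        reads = filter_exact_contaminant(reads, cfg.contaminant)
    stage_counts["post_depletion_total"] = reads.total_count

    # RPM denominator: 0-mismatch genome-mapped mass of the full
    # post-depletion library (before piRNA size selection)
    composition = None
    if genome is not None:
        genome_index = ReferenceIndex(genome)
        genome_map = genome_unique_status(reads, genome_index)
        normalization_total = genome_map.mapped_total
        stage_counts["genome_mapped_0mm_total"] = normalization_total
    else:
        normalization_total = reads.total_count
        stage_counts["genome_mapped_0mm_total"] = -1

    pirnas = reads.filter_lengths(cfg.pirna_min_len, cfg.pirna_max_len)
    stage_counts["pirna_total"] = pirnas.total_count

    te_map = map_reads(pirnas, te, max_mismatches=cfg.max_mismatches_te, report="best")
    alns = best_placements(te_map)
    stage_counts["te_mapped_total"] = te_map.mapped_total

    report = signature_report(alns, include_self=cfg.z_include_self)
    hist = overlap_histogram(alns)
    window = _window_for(te_name, cfg, te_length)
    profile = density_profile(
        alns, te_length, window, max(1, normalization_total), target=te_name
    )
    if genome is not None and clusters is not None and len(clusters) > 0:
        pirna_genome_map = genome_unique_status(pirnas, genome_index)
        composition = cluster_composition(pirna_genome_map, clusters)

    result = SignatureResult(
        report=report,
        histogram=hist,
        profile=profile,
        composition=composition,
        normalization_total=normalization_total,
        stage_counts=stage_counts,
    )
    if outdir is not None:
        _write_signature_reports(result, te_name, cfg, outdir)
    return result


def _write_signature_reports(
    result: SignatureResult, te_name: str, cfg: SignatureConfig, outdir: str
) -> None:
    os.makedirs(outdir, exist_ok=True)
    result.histogram.to_frame().to_csv(
        os.path.join(outdir, "overlap_histogram.tsv"), sep="\t", index=False
    )
    result.report.to_frame().to_csv(
        os.path.join(outdir, "signature_report.tsv"), sep="\t", index=False
    )
    result.profile.to_frame().to_csv(
        os.path.join(outdir, "density_profile.tsv"), sep="\t", index=False
    )
    if result.composition is not None:
        result.composition.to_frame(include_unassigned=True).to_csv(
            os.path.join(outdir, "cluster_composition.tsv"), sep="\t", index=False
        )
    manifest = {
        "tool": "pirnakit",
        "version": __version__,
        "pipeline": "signature",
        "te": te_name,
        "parameters": asdict(cfg),
        "stage_counts": result.stage_counts,
        "normalization_total": result.normalization_total,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class InsertionConfig:
    junction: JunctionParams = field(default_factory=JunctionParams)
    insert_prior: InsertSizePrior = field(default_factory=InsertSizePrior)
    cluster_distance: int = 500
    min_support: int = 2


def run_insertion_pipeline(
    pairs: list | tuple[str, str],
    te: ReferenceSet | str,
    genome: ReferenceSet | str,
    clusters: IntervalSet | str | None = None,
    cfg: InsertionConfig = InsertionConfig(),
    outdir: str | None = None,
) -> list:
    """Run chimeric-read + discordant-pair insertion detection."""
    if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], str):
        pairs = load_fastq_pairs(*pairs)
    if isinstance(te, str):
        te = load_references(te)
    if isinstance(genome, str):
        genome = load_references(genome)
    if isinstance(clusters, str):
        clusters = load_intervals(clusters)

    index = ReferenceIndex(genome)
    junctions = find_junction_reads(pairs, te, index, cfg.junction)
    discordants = find_discordant_pairs(pairs, te, index, cfg.insert_prior)
    candidates = call_insertions(
        junctions, discordants, genome,
        cluster_distance=cfg.cluster_distance, min_support=cfg.min_support,
    )
    if clusters is not None:
        candidates = annotate_candidates(candidates, clusters)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_candidates_tsv(candidates, os.path.join(outdir, "candidates.tsv"))
        write_candidates_bed(candidates, os.path.join(outdir, "candidates.bed"))
        manifest = {
            "tool": "pirnakit",
            "version": __version__,
            "pipeline": "insertion",
            "parameters": {
                "junction": asdict(cfg.junction),
                "insert_prior": asdict(cfg.insert_prior),
                "cluster_distance": cfg.cluster_distance,
                "min_support": cfg.min_support,
            },
            "counts": {
                "pairs": len(pairs),
                "junction_reads": len(junctions),
                "discordant_pairs": len(discordants),
                "candidates": len(candidates),
            },
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return candidates
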