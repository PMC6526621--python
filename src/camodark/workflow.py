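"""End-to-end composition of the detection + rescue pipeline.

Glue for the common full run on one genome: scan reads for dark
regions, snap dark-by-MAPQ cores to the camouflaged CDS exons, discover
camo sets, plan the reference masking, screen reference-based
artifacts, and rescue variants from every set at its ploidy.  The CLI,
the examples and the acceptance checks all drive this module so they
exercise the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotate import GeneModel, flatten_gene_models
from .artifacts import ArtifactPosition, artifact_position_set, screen_artifacts
from .camo import (
    CamoSet,
    KmerIndex,
    MaskPlan,
    build_camo_sets,
    camo_candidate_regions,
    find_similar_regions,
    plan_masking,
)
from .formats import AlignedRead, GenomeSequence, TranscriptRecord
from .rescue import RescueConfig, RescuedVariant, rescue_camo_set
from .scan import (
    DARK_BY_MAPQ,
    DarkRegion,
    DarkScanConfig,
    PositionSummary,
    build_dark_regions,
    classify_summaries,
    scan_sample_arrays,
)

__all__ = [
    "PipelineResult",
    "scan_dark_regions",
    "run_rescue_pipeline",
    "three_exon_study_spec",
]


def three_exon_study_spec(seed: int, with_variant: bool = True):
    """Study conditions for the three-identical-exons rescue scenario.

    One gene carries a 3-copy intra-gene duplication family (300-nt CDS
    exons, ~99.3% identity with the divergent sites near the left exon
    edge so a contiguous dark core survives), sequenced at ~40x per copy
    with 100-nt reads; the planted variant is a heterozygous 10-nt
    frameshift deletion in the middle of the second copy.  Pooled over
    6 haplotypes the expected alt fraction is 1/6.
    """
    from .sim import DuplicationFamily, PlantedVariant, SimSpec

    variants = (
        (PlantedVariant(family=0, copy_index=1, offset=150, deletion_length=10),)
        if with_variant
        else ()
    )
    return SimSpec(
        genome_length=9_000,
        mean_depth=40.0,
        families=(
            DuplicationFamily(
                copy_count=3,
                segment_length=300,
                identity_pct=99.3,
                intra_gene=True,
                divergence_zone=(10, 45),
            ),
        ),
        variants=variants,
        seed=seed,
    )


@dataclass
class PipelineResult:
    dark_regions: list[DarkRegion]
    camo_sets: list[CamoSet]
    mask_plan: Optional[MaskPlan]
    masked_genome: Optional[GenomeSequence]
    artifact_positions: list[ArtifactPosition]
    skipped_sets: list[str]
    variants: list[RescuedVariant]
    call_summaries: dict[str, dict] = field(default_factory=dict)

    @property
    def pass_variants(self) -> list[RescuedVariant]:
        return [v for v in self.variants if v.is_pass]


def scan_dark_regions(
    per_sample_reads: Sequence[Sequence[AlignedRead]],
    genome: GenomeSequence,
    config: DarkScanConfig = DarkScanConfig(),
) -> tuple[list[DarkRegion], dict[str, np.ndarray]]:
    """Scan one or more samples; returns regions + low-MAPQ mass arrays.

    Depth and low-MAPQ counts are averaged across samples per position
    before the thresholds are applied.
    """
    regions: list[DarkRegion] = []
    mass: dict[str, np.ndarray] = {}
    for contig in genome.contigs:
        n = genome.length(contig)
        depth = np.zeros(n)
        low = np.zeros(n)
        for reads in per_sample_reads:
            d, l = scan_sample_arrays(reads, contig, (0, n), config)
            depth += d
            low += l
        depth /= len(per_sample_reads)
        low /= len(per_sample_reads)
        with np.errstate(invalid="ignore", divide="ignore"):
            mass[contig] = np.where(depth > 0, low / np.where(depth > 0, depth, 1), 0.0)
        summaries = [
            PositionSummary(contig, i, float(depth[i]), float(low[i]))
            for i in range(n)
        ]
        regions.extend(build_dark_regions(classify_summaries(summaries, config), config))
    return regions, mass


def run_rescue_pipeline(
    per_sample_reads: Sequence[Sequence[AlignedRead]],
    genome: GenomeSequence,
    transcripts: Sequence[TranscriptRecord],
    scan_config: DarkScanConfig = DarkScanConfig(),
    rescue_config: RescueConfig = RescueConfig(),
    gene_models: Optional[Sequence[GeneModel]] = None,
) -> PipelineResult:
    """Scan -> camo discovery -> mask -> artifact screen -> rescue."""
    if gene_models is None:
        gene_models = flatten_gene_models(transcripts)
    dark_regions, mass = scan_dark_regions(per_sample_reads, genome, scan_config)
    mapq_regions = [r for r in dark_regions if r.klass == DARK_BY_MAPQ]
    candidates = camo_candidate_regions(mapq_regions, gene_models)
    if not candidates:
        return PipelineResult(dark_regions, [], None, None, [], [], [])
    index = KmerIndex(genome)
    hits = {
        i: find_similar_regions(
            (r.contig, r.start, r.end), genome, index=index
        )
        for i, r in enumerate(candidates)
    }
    gene_spans = [(g.contig, *g.span) for g in gene_models]
    sets = build_camo_sets(candidates, hits, mass, scan_config, gene_spans)
    if not sets:
        return PipelineResult(dark_regions, [], None, None, [], [], [])
    mask_plan, masked_genome, _ = plan_masking(sets, genome)
    artifact_positions, skipped = screen_artifacts(sets, genome)
    artifact_set = artifact_position_set(artifact_positions)
    all_reads = [r for reads in per_sample_reads for r in reads]
    variants: list[RescuedVariant] = []
    call_summaries: dict[str, dict] = {}
    for s in sets:
        vs, summary = rescue_camo_set(
            all_reads, s, masked_genome, artifact_set, rescue_config
        )
        variants.extend(vs)
        call_summaries[s.set_id] = summary
    return PipelineResult(
        dark_regions,
        sets,
        mask_plan,
        masked_genome,
        artifact_positions,
        skipped,
        variants,
        call_summaries,
    )
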