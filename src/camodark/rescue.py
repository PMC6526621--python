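"""Camouflaged-variant rescue.

The rescue pipeline pools the ambiguously mapped evidence of a camo set
onto its single unmasked representative region and calls variants there
at elevated ploidy:

1. extract all reads with MAPQ < 10 from every region of the set,
2. realign them (glocal, affine gaps) to the representative's
   neighbourhood in the masked reference — with every competing copy
   masked the placement is unique, so accepted reads carry high MAPQ,
3. call genotypes per column under a pooled-haplotype model: with P =
   2 x repeat_count haplotypes and k alt copies, each read's base is an
   independent draw that shows the alt with probability
   (k/P)(1-eps) + (1-k/P) eps,
4. filter calls at reference-based artifact positions and calls with
   low quality-by-depth (QD <= 2 by default, <= 3 stringent).

A heterozygous variant in one copy of a three-copy set is expected in
~1/6 of pooled reads, which is why the diploid assumption must be
replaced by the set's ploidy.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .alignment import ScoringScheme, align
from .camo import CamoSet, Interval
from .formats import AlignedRead, GenomeSequence

__all__ = [
    "RescueConfig",
    "RescuedVariant",
    "extract_low_mapq_reads",
    "realign_to_masked",
    "genotype_log_likelihoods",
    "call_genotype",
    "call_variants_ploidy",
    "filter_rescued",
    "rescue_camo_set",
]

_MAX_QUAL = 9999.0


@dataclass(frozen=True)
class RescueConfig:
    """Parameters of the extract/realign/call/filter stages.

    ``base_error_rate`` is the per-base substitution error assumed for
    the reads (0.001, i.e. Q30); ``indel_error_rate`` is the chance a
    read displays a spurious alignment gap (indel sequencing errors are
    far rarer than substitutions); ``variant_prior`` is the prior
    probability that a site is variant, split uniformly over the
    nonzero alt copy numbers (the standard heterozygosity-style prior —
    it stops a lone mismatching read at a shallow column from becoming
    a call).
    """

    extract_mapq_max: int = 9
    base_error_rate: float = 0.001
    indel_error_rate: float = 1e-5
    variant_prior: Optional[float] = 1e-3
    qd_min: float = 2.0
    score_floor_frac: float = 0.5  # of the perfect-match read score
    realign_pad: int = 150
    scoring: ScoringScheme = ScoringScheme()

    def __post_init__(self) -> None:
        if not 0.0 < self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must be in (0, 0.5)")
        if not 0.0 < self.indel_error_rate < 0.5:
            raise ValueError("indel_error_rate must be in (0, 0.5)")
        if self.qd_min < 0:
            raise ValueError("qd_min must be >= 0")


@dataclass
class RescuedVariant:
    contig: str
    pos: int  # 0-based, left-anchored for indels
    ref_allele: str
    alt_allele: str
    alt_count: int
    ploidy: int
    depth: int
    qual: float
    set_id: str = ""
    filters: set[str] = field(default_factory=set)

    @property
    def qd(self) -> float:
        return self.qual / self.depth if self.depth else 0.0

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_pass(self) -> bool:
        return not self.filters


def extract_low_mapq_reads(
    alignments: Iterable[AlignedRead],
    camo_set: CamoSet,
    config: RescueConfig = RescueConfig(),
) -> list[AlignedRead]:
    """Union of MAPQ <= threshold reads over all regions of the set.

    Reads are deduplicated by name (a read overlapping two mate regions
    is emitted once).
    """
    seen: set[str] = set()
    out: list[AlignedRead] = []
    for read in alignments:
        if read.mapq > config.extract_mapq_max:
            continue
        if read.name in seen:
            continue
        for contig, start, end in camo_set.regions:
            if read.contig == contig and read.overlaps(start, end):
                seen.add(read.name)
                out.append(read)
                break
    return out


def realign_to_masked(
    reads: Sequence[AlignedRead],
    masked_ref: GenomeSequence,
    representative: Interval,
    config: RescueConfig = RescueConfig(),
) -> list[AlignedRead]:
    """Glocal-realign extracted reads to the representative neighbourhood.

    Each read is aligned end to end against the representative region
    plus ``realign_pad`` flanks; terminal query-only columns become soft
    clips.  Reads scoring below ``score_floor_frac`` of a perfect match
    are discarded.  Accepted reads get MAPQ 60: with all competing
    copies masked there is a single candidate locus.
    """
    contig, rstart, rend = representative
    if contig not in masked_ref.contigs:
        raise KeyError(f"contig {contig!r} absent from masked reference")
    wstart = max(0, rstart - config.realign_pad)
    wend = min(masked_ref.length(contig), rend + config.realign_pad)
    window = masked_ref.fetch(contig, wstart, wend)
    out: list[AlignedRead] = []
    for read in reads:
        if not read.sequence:
            continue
        aln = align(read.sequence, window, config.scoring, mode="fit")
        floor = config.score_floor_frac * config.scoring.match * len(read.sequence)
        if aln.score < floor or not aln.columns:
            continue
        cigar = aln.cigar()
        # terminal insertions are unaligned read ends -> soft clips
        if cigar and cigar[0][0] == "I":
            cigar[0] = ("S", cigar[0][1])
        if cigar and cigar[-1][0] == "I":
            cigar[-1] = ("S", cigar[-1][1])
        # terminal deletions carry no read evidence; trim them
        start_off = aln.subject_start
        if cigar and cigar[0][0] == "D":
            start_off += cigar[0][1]
            cigar = cigar[1:]
        if cigar and cigar[-1][0] == "D":
            cigar = cigar[:-1]
        out.append(
            AlignedRead(
                name=read.name,
                contig=contig,
                start=wstart + start_off,
                mapq=60,
                cigar=cigar,
                sequence=read.sequence,
                base_quals=read.base_quals,
            )
        )
    out.sort(key=lambda r: r.start)
    return out


def genotype_log_likelihoods(
    n_alt: int, n_ref: int, ploidy: int, eps: float
) -> np.ndarray:
    """Log-likelihood of each alt copy number k = 0..ploidy.

    Under k alt copies of P pooled haplotypes, a read drawn uniformly
    from the haplotypes shows the alt allele with probability
    (k/P)(1-eps) + (1-k/P) eps and the ref allele otherwise.
    """
    k = np.arange(ploidy + 1)
    p_alt = (k / ploidy) * (1 - eps) + (1 - k / ploidy) * eps
    return n_alt * np.log(p_alt) + n_ref * np.log1p(-p_alt)


def call_genotype(
    n_alt: int,
    n_ref: int,
    ploidy: int,
    eps: float,
    variant_prior: Optional[float] = None,
) -> tuple[int, float]:
    """(k*, qual): most probable alt copy number and phred confidence.

    With ``variant_prior`` None the prior over k is flat, so k* is the
    maximum-likelihood copy number.  Otherwise P(k=0) = 1 - prior and
    the prior mass is split uniformly over k = 1..P.  ``qual`` is the
    phred-scaled posterior mass on k = 0, i.e. the confidence that the
    site carries at least one alt copy.
    """
    ll = genotype_log_likelihoods(n_alt, n_ref, ploidy, eps)
    if variant_prior is not None:
        log_prior = np.full(ploidy + 1, math.log(variant_prior / ploidy))
        log_prior[0] = math.log1p(-variant_prior)
        ll = ll + log_prior
    k_star = int(np.argmax(ll))
    log_post0 = ll[0] - logsumexp(ll)
    qual = min(_MAX_QUAL, -10.0 * log_post0 / math.log(10.0))
    return k_star, qual


def _pileup(
    alignments: Sequence[AlignedRead], region: Interval
) -> tuple[dict[int, Counter], dict[tuple[int, int], int], dict[tuple[int, str], int], list[tuple[int, int]]]:
    """Column bases, deletion events, insertion events and footprints."""
    contig, start, end = region
    bases: dict[int, Counter] = defaultdict(Counter)
    deletions: dict[tuple[int, int], int] = defaultdict(int)
    insertions: dict[tuple[int, str], int] = defaultdict(int)
    footprints: list[tuple[int, int]] = []
    for read in alignments:
        if read.contig != contig:
            continue
        rpos, qpos = read.start, 0
        for op, n in read.cigar:
            if op in "M=X":
                for i in range(n):
                    p = rpos + i
                    if start <= p < end:
                        bases[p][read.sequence[qpos + i]] += 1
                rpos += n
                qpos += n
            elif op in "DN":
                if start <= rpos < end:
                    deletions[(rpos, n)] += 1
                rpos += n
            elif op == "I":
                if start <= rpos < end:
                    insertions[(rpos, read.sequence[qpos : qpos + n])] += 1
                qpos += n
            elif op in "SH":
                if op == "S":
                    qpos += n
        footprints.append((read.start, read.end))
    return bases, deletions, insertions, footprints


def _left_normalize_deletions(
    deletions: dict[tuple[int, int], int], ref: str
) -> dict[tuple[int, int], int]:
    """Shift deletion events to their left-most equivalent placement.

    Gap placement inside a repeat is ambiguous; normalizing merges
    equivalent events reported at different offsets by different reads.
    """
    out: dict[tuple[int, int], int] = defaultdict(int)
    for (dpos, dlen), n in deletions.items():
        while dpos > 0 and ref[dpos - 1] == ref[dpos + dlen - 1]:
            dpos -= 1
        out[(dpos, dlen)] += n
    return dict(out)


def _left_normalize_insertions(
    insertions: dict[tuple[int, str], int], ref: str
) -> dict[tuple[int, str], int]:
    out: dict[tuple[int, str], int] = defaultdict(int)
    for (ipos, seq), n in insertions.items():
        while ipos > 0 and ref[ipos - 1] == seq[-1]:
            seq = ref[ipos - 1] + seq[:-1]
            ipos -= 1
        out[(ipos, seq)] += n
    return dict(out)


def call_variants_ploidy(
    alignments: Sequence[AlignedRead],
    masked_ref: GenomeSequence,
    region: Interval,
    ploidy: int,
    config: RescueConfig = RescueConfig(),
    set_id: str = "",
) -> list[RescuedVariant]:
    """Call pooled-ploidy variants over ``region`` from realigned reads.

    SNVs are called per column from ref/alt base counts; indels from
    alignment gap events, with spanning reads as the denominator.
    Zero-depth columns yield no call.  Variants are emitted where the
    maximum-likelihood alt copy number k* >= 1.
    """
    if ploidy < 2 or ploidy % 2:
        raise ValueError("ploidy must be even and >= 2")
    contig, start, end = region
    ref = masked_ref[contig]
    bases, deletions, insertions, footprints = _pileup(alignments, region)
    deletions = _left_normalize_deletions(deletions, ref)
    insertions = _left_normalize_insertions(insertions, ref)
    variants: list[RescuedVariant] = []
    for pos in sorted(bases):
        counts = bases[pos]
        ref_base = ref[pos]
        n_ref = counts.get(ref_base, 0)
        alts = [(c, b) for b, c in counts.items() if b != ref_base and b != "N"]
        if not alts:
            continue
        n_alt, alt_base = max(alts)
        depth = n_ref + n_alt
        if depth == 0:
            continue
        k_star, qual = call_genotype(
            n_alt, n_ref, ploidy, config.base_error_rate, config.variant_prior
        )
        if k_star >= 1:
            variants.append(
                RescuedVariant(
                    contig, pos, ref_base, alt_base, k_star, ploidy, depth, qual, set_id
                )
            )
    for (dpos, dlen), n_alt in sorted(deletions.items()):
        anchor = dpos - 1
        if anchor < 0:
            continue
        n_span = sum(1 for fs, fe in footprints if fs <= anchor and fe >= dpos + dlen)
        n_ref = max(0, n_span - n_alt)
        depth = n_alt + n_ref
        if depth == 0:
            continue
        k_star, qual = call_genotype(
            n_alt, n_ref, ploidy, config.indel_error_rate, config.variant_prior
        )
        if k_star >= 1:
            variants.append(
                RescuedVariant(
                    contig,
                    anchor,
                    ref[anchor : dpos + dlen],
                    ref[anchor],
                    k_star,
                    ploidy,
                    depth,
                    qual,
                    set_id,
                )
            )
    for (ipos, ins_seq), n_alt in sorted(insertions.items()):
        anchor = ipos - 1
        if anchor < 0:
            continue
        n_span = sum(1 for fs, fe in footprints if fs <= anchor and fe > ipos)
        n_ref = max(0, n_span - n_alt)
        depth = n_alt + n_ref
        if depth == 0:
            continue
        k_star, qual = call_genotype(
            n_alt, n_ref, ploidy, config.indel_error_rate, config.variant_prior
        )
        if k_star >= 1:
            variants.append(
                RescuedVariant(
                    contig,
                    anchor,
                    ref[anchor],
                    ref[anchor] + ins_seq,
                    k_star,
                    ploidy,
                    depth,
                    qual,
                    set_id,
                )
            )
    variants.sort(key=lambda v: v.pos)
    return variants


def filter_rescued(
    variants: Sequence[RescuedVariant],
    artifact_positions: Iterable[tuple[str, int]],
    config: RescueConfig = RescueConfig(),
) -> tuple[list[RescuedVariant], dict]:
    """Annotate artifact / low-QD filters; report PASS Ti/Tv.

    A variant is an artifact when any reference base it spans is a known
    reference-divergence position of its camo set.  QD <= ``qd_min`` is
    flagged ``low_qd``.
    """
    artifacts = set(artifact_positions)
    out: list[RescuedVariant] = []
    for v in variants:
        filters = set(v.filters)
        if any((v.contig, p) in artifacts for p in range(v.pos, v.pos + len(v.ref_allele))):
            filters.add("artifact")
        if v.qd <= config.qd_min:
            filters.add("low_qd")
        out.append(
            RescuedVariant(
                v.contig,
                v.pos,
                v.ref_allele,
                v.alt_allele,
                v.alt_count,
                v.ploidy,
                v.depth,
                v.qual,
                v.set_id,
                filters,
            )
        )
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    n_ti = n_tv = 0
    for v in out:
        if v.is_pass and v.is_snv:
            if (v.ref_allele, v.alt_allele) in transitions:
                n_ti += 1
            else:
                n_tv += 1
    summary = {
        "n_total": len(out),
        "n_pass": sum(1 for v in out if v.is_pass),
        "n_transitions": n_ti,
        "n_transversions": n_tv,
        "titv": (n_ti / n_tv) if n_tv else None,
    }
    return out, summary


def rescue_camo_set(
    alignments: Iterable[AlignedRead],
    camo_set: CamoSet,
    masked_ref: GenomeSequence,
    artifact_positions: Iterable[tuple[str, int]] = (),
    config: RescueConfig = RescueConfig(),
    restrict_to: Optional[Sequence[Interval]] = None,
) -> tuple[list[RescuedVariant], dict]:
    """Run the full per-set rescue: extract, realign, call, filter.

    ``restrict_to`` limits calling to the given intervals (CDS exons by
    default upstream); when omitted the representative region is used.
    """
    extracted = extract_low_mapq_reads(alignments, camo_set, config)
    realigned = realign_to_masked(extracted, masked_ref, camo_set.representative, config)
    regions = list(restrict_to) if restrict_to else [camo_set.representative]
    variants: list[RescuedVariant] = []
    for region in regions:
        variants.extend(
            call_variants_ploidy(
                realigned,
                masked_ref,
                region,
                camo_set.ploidy,
                config,
                camo_set.set_id,
            )
        )
    return filter_rescued(variants, artifact_positions, config)
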