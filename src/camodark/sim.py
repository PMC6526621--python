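"""Synthetic genomes, reads and truth sets for dark/camouflaged analysis.

The generator emulates the data conditions the detection framework was
designed for: a diploid genome carrying families of near-identical
duplicated segments (tunable percent identity), standard short reads
(100 nt) at ~37.5x mean depth, and an aligner that, when a read matches
two or more copies equally well, places it uniformly at random among
them with MAPQ 0 while uniquely placeable reads get MAPQ 60.

Reads are emitted already "aligned" (the multi-mapping rule is applied
by the simulator itself), so no external aligner is needed; the same
reads can be written to SAM for CLI-level runs.  Equal-best placement
is decided by reference-footprint identity: a read placed at p is
ambiguous iff the reference sequence under its alignment footprint at p
is byte-identical at the homologous offset of another copy.  For reads
without planted variants this coincides with exact substring equality
of the (error-free) read against each copy; for variant-carrying reads
it reproduces what a score-based aligner would do.  Sequencing errors
are applied after placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats import AlignedRead, GenomeSequence, TranscriptRecord

__all__ = [
    "DuplicationFamily",
    "PlantedVariant",
    "SimSpec",
    "FamilyTruth",
    "VariantTruth",
    "SimTruth",
    "simulate_genome",
    "simulate_reads",
    "plant_variant",
    "expected_dark_mapq_intervals",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ALPHABET = "ACGT"


@dataclass(frozen=True)
class DuplicationFamily:
    """A family of duplicated segments written into the genome.

    ``divergence_zone`` optionally restricts where (segment offsets) the
    divergent substitutions of non-representative copies may fall;
    placing them near one segment edge leaves a long identical core, the
    situation that produces a contiguous dark-by-MAPQ region under
    short reads.
    """

    copy_count: int = 2
    segment_length: int = 300
    identity_pct: float = 100.0
    intra_gene: bool = False
    divergence_zone: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.copy_count < 2:
            raise ValueError("copy_count must be >= 2")
        if self.identity_pct < 90.0 or self.identity_pct > 100.0:
            raise ValueError("identity_pct must be in [90, 100]")

    @property
    def n_divergent_sites(self) -> int:
        """Substitutions per non-representative copy, by construction."""
        return round((1.0 - self.identity_pct / 100.0) * self.segment_length)


@dataclass(frozen=True)
class PlantedVariant:
    """A variant planted on one haplotype of one duplication copy.

    For a SNV set ``alt``; for a deletion set ``deletion_length``.
    ``offset`` is relative to the segment start.
    """

    family: int = 0
    copy_index: int = 0
    offset: int = 0
    alt: Optional[str] = None
    deletion_length: int = 0
    homozygous: bool = False

    @property
    def kind(self) -> str:
        return "deletion" if self.deletion_length > 0 else "snv"


@dataclass(frozen=True)
class SimSpec:
    genome_length: int = 20_000
    families: tuple[DuplicationFamily, ...] = (DuplicationFamily(),)
    variants: tuple[PlantedVariant, ...] = ()
    read_length: int = 100
    mean_depth: float = 37.5
    error_rate: float = 0.001
    dropout_windows: tuple[tuple[int, int], ...] = ()
    contig: str = "chr1"
    seed: int = 0


@dataclass
class FamilyTruth:
    copies: list[tuple[int, int]]
    intra_gene: bool
    # divergence[copy_index][offset] = (segment_base, divergent_base)
    divergence: dict[int, dict[int, tuple[str, str]]]

    def divergent_genome_positions(self) -> list[tuple[int, int, str, str]]:
        """(copy_index, genome_pos, copy_base, representative_base) rows."""
        out = []
        for ci, sites in self.divergence.items():
            start = self.copies[ci][0]
            for off, (ref_base, alt_base) in sorted(sites.items()):
                out.append((ci, start + off, alt_base, ref_base))
        return out


@dataclass
class VariantTruth:
    family: int
    copy_index: int
    genome_pos: int  # position within the carrying copy
    kind: str
    alt: str
    deletion_length: int
    expected_alt_fraction: float
    homozygous: bool


@dataclass
class SimTruth:
    contig: str
    genome_length: int
    read_length: int
    families: list[FamilyTruth] = field(default_factory=list)
    variants: list[VariantTruth] = field(default_factory=list)
    dropout_windows: list[tuple[int, int]] = field(default_factory=list)

    def copy_intervals(self) -> list[tuple[int, int]]:
        return [iv for fam in self.families for iv in fam.copies]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _ALPHABET if b != base]
    return choices[rng.integers(len(choices))]


def simulate_genome(
    spec: SimSpec,
) -> tuple[GenomeSequence, list[TranscriptRecord], SimTruth]:
    """Build the reference genome, gene models and truth set.

    Duplication copies are laid out left to right with unique random
    flanks between them.  Divergent sites are substitutions placed away
    from segment edges (>= 10 nt) with >= 5 nt separation, so each is
    recoverable as its own alignment column.  Each intra-gene family
    becomes one gene whose camo segments are CDS exons (the three-
    identical-exons scenario); each copy of a non-intra-gene family
    becomes the single CDS exon of its own gene.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_seq(rng, spec.genome_length))
    truth = SimTruth(
        contig=spec.contig,
        genome_length=spec.genome_length,
        read_length=spec.read_length,
        dropout_windows=list(spec.dropout_windows),
    )
    gap = max(3 * spec.read_length, 400)
    cursor = gap
    for fam in spec.families:
        segment = _random_seq(rng, fam.segment_length)
        copies: list[tuple[int, int]] = []
        divergence: dict[int, dict[int, tuple[str, str]]] = {}
        for ci in range(fam.copy_count):
            start = cursor
            end = start + fam.segment_length
            if end + gap > spec.genome_length:
                raise ValueError(
                    "genome_length too small for requested families/flanks"
                )
            copy_seq = list(segment)
            if ci > 0 and fam.n_divergent_sites > 0:
                sites = _pick_separated_offsets(
                    rng,
                    fam.segment_length,
                    fam.n_divergent_sites,
                    zone=fam.divergence_zone,
                )
                divergence[ci] = {}
                for off in sites:
                    alt = _other_base(rng, segment[off])
                    copy_seq[off] = alt
                    divergence[ci][off] = (segment[off], alt)
            seq[start:end] = copy_seq
            copies.append((start, end))
            cursor = end + gap
        truth.families.append(
            FamilyTruth(copies=copies, intra_gene=fam.intra_gene, divergence=divergence)
        )
    for var in spec.variants:
        plant_variant(truth, var)
    genome = GenomeSequence({spec.contig: "".join(seq)})
    transcripts = _gene_models_for(spec, truth)
    return genome, transcripts, truth


def _pick_separated_offsets(
    rng: np.random.Generator,
    seg_len: int,
    n: int,
    edge: int = 10,
    min_sep: int = 5,
    zone: Optional[tuple[int, int]] = None,
) -> list[int]:
    lo, hi = edge, seg_len - edge
    if zone is not None:
        lo, hi = max(lo, zone[0]), min(hi, zone[1])
    if hi - lo < n * min_sep:
        raise ValueError("identity unreachable for segment length")
    for _ in range(200):
        offs = sorted(rng.choice(np.arange(lo, hi), size=n, replace=False).tolist())
        if all(b - a >= min_sep for a, b in zip(offs, offs[1:])):
            return offs
    raise ValueError("could not place divergent sites with required separation")


def plant_variant(truth: SimTruth, var: PlantedVariant) -> SimTruth:
    """Record a planted variant in the truth set (validating placement)."""
    fam = truth.families[var.family]
    start, end = fam.copies[var.copy_index]
    seg_len = end - start
    if not 0 <= var.offset < seg_len:
        raise ValueError("variant offset outside segment")
    if var.kind == "deletion" and var.offset + var.deletion_length > seg_len:
        raise ValueError("deletion runs past segment end")
    div_sites = set(fam.divergence.get(var.copy_index, {}))
    span = range(var.offset, var.offset + max(var.deletion_length, 1))
    if any(off in div_sites for off in span):
        raise ValueError("variant collides with a planted divergence site")
    copy_count = len(fam.copies)
    n_hap = 2 if var.homozygous else 1
    truth.variants.append(
        VariantTruth(
            family=var.family,
            copy_index=var.copy_index,
            genome_pos=start + var.offset,
            kind=var.kind,
            alt=var.alt or "",
            deletion_length=var.deletion_length,
            expected_alt_fraction=n_hap / (2 * copy_count),
            homozygous=var.homozygous,
        )
    )
    return truth


def _gene_models_for(spec: SimSpec, truth: SimTruth) -> list[TranscriptRecord]:
    transcripts: list[TranscriptRecord] = []
    utr_len = 60
    gi = 0
    for fi, fam in enumerate(truth.families):
        if fam.intra_gene:
            gi += 1
            first = fam.copies[0][0]
            feats: list[tuple[str, tuple[int, int]]] = [
                ("exon", (first - utr_len, first)),
                ("five_prime_utr", (first - utr_len, first)),
            ]
            for start, end in fam.copies:
                feats.append(("exon", (start, end)))
                feats.append(("CDS", (start, end)))
            transcripts.append(
                TranscriptRecord(
                    gene_id=f"GENE{gi}",
                    gene_symbol=f"CAMO{fi}",
                    biotype="protein_coding",
                    transcript_id=f"TX{gi}",
                    contig=spec.contig,
                    strand="+",
                    features=feats,
                )
            )
        else:
            for ci, (start, end) in enumerate(fam.copies):
                gi += 1
                feats = [
                    ("exon", (start - utr_len, start)),
                    ("five_prime_utr", (start - utr_len, start)),
                    ("exon", (start, end)),
                    ("CDS", (start, end)),
                ]
                transcripts.append(
                    TranscriptRecord(
                        gene_id=f"GENE{gi}",
                        gene_symbol=f"CAMO{fi}_{ci}",
                        biotype="protein_coding",
                        transcript_id=f"TX{gi}",
                        contig=spec.contig,
                        strand="+",
                        features=feats,
                    )
                )
    return transcripts


# ---------------------------------------------------------------------------
# read simulation


def _haplotype_variants(truth: SimTruth) -> dict[int, list[VariantTruth]]:
    """Map haplotype index (0/1) to the variants it carries."""
    out: dict[int, list[VariantTruth]] = {0: [], 1: []}
    for v in truth.variants:
        out[0].append(v)
        if v.homozygous:
            out[1].append(v)
    return out


def _build_read(
    genome_seq: str,
    start: int,
    read_len: int,
    variants: Sequence[VariantTruth],
) -> Optional[tuple[str, list[tuple[str, int]], int]]:
    """Assemble (sequence, cigar, ref_end) for a read starting at ``start``.

    Walks the reference applying any haplotype variants whose footprint
    is reached; returns None when the contig ends before the read fills.
    """
    dels = sorted(
        (v.genome_pos, v.genome_pos + v.deletion_length)
        for v in variants
        if v.kind == "deletion"
    )
    snvs = {v.genome_pos: v.alt for v in variants if v.kind == "snv"}
    seq: list[str] = []
    cigar: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n == 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    pos = start
    # a read cannot start inside a deleted interval on this haplotype
    for ds, de in dels:
        if ds <= pos < de:
            return None
    while len(seq) < read_len:
        if pos >= len(genome_seq):
            return None
        in_del = next(((ds, de) for ds, de in dels if ds <= pos < de), None)
        if in_del is not None:
            ds, de = in_del
            push("D", de - pos)
            pos = de
            continue
        base = snvs.get(pos, genome_seq[pos])
        seq.append(base)
        push("M", 1)
        pos += 1
    # drop a trailing D (deletion at the very end of a read is unobservable)
    if cigar and cigar[-1][0] == "D":
        pos -= cigar[-1][1]
        cigar.pop()
    return "".join(seq), cigar, pos


def simulate_reads(
    genome: GenomeSequence,
    truth: SimTruth,
    spec: SimSpec,
    rng: Optional[np.random.Generator] = None,
    regions: Optional[Sequence[tuple[int, int]]] = None,
) -> list[AlignedRead]:
    """Draw reads at ``spec.mean_depth`` and apply the multi-mapping rule.

    ``regions`` optionally restricts read start positions to the given
    intervals (e.g. a camo neighbourhood), otherwise the whole contig is
    sampled.  Reads whose footprint overlaps a dropout window are
    suppressed, producing dark-by-depth truth.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    contig = truth.contig
    ref = genome[contig]
    L = spec.read_length
    hap_vars = _haplotype_variants(truth)
    if regions is None:
        regions = [(0, truth.genome_length)]
    reads: list[AlignedRead] = []
    ridx = 0
    for rstart, rend in regions:
        span = rend - rstart
        n_reads = int(round(spec.mean_depth * span / L))
        starts = rng.integers(rstart, max(rstart + 1, rend - L), size=n_reads)
        haps = rng.integers(0, 2, size=n_reads)
        for start, hap in zip(starts.tolist(), haps.tolist()):
            built = _build_read(ref, start, L, hap_vars[int(hap)])
            if built is None:
                continue
            seq, cigar, ref_end = built
            if any(start < de and ref_end > ds for ds, de in truth.dropout_windows):
                continue
            placements = _equal_best_placements(ref, truth, start, cigar)
            if len(placements) > 1:
                mapped = int(placements[rng.integers(len(placements))])
                mapq = 0
            else:
                mapped = start
                mapq = 60
            seq = _apply_errors(rng, seq, spec.error_rate)
            reads.append(
                AlignedRead(
                    name=f"r{ridx}",
                    contig=contig,
                    start=mapped,
                    mapq=mapq,
                    cigar=list(cigar),
                    sequence=seq,
                )
            )
            ridx += 1
    reads.sort(key=lambda r: r.start)
    return reads


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    flips = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(flips) == 0:
        return seq
    out = list(seq)
    for i in flips.tolist():
        out[i] = _other_base(rng, out[i])
    return "".join(out)


def _footprint_blocks(start: int, cigar: Sequence[tuple[str, int]]) -> list[tuple[int, int]]:
    blocks = []
    pos = start
    for op, n in cigar:
        if op in "M=X":
            blocks.append((pos, pos + n))
            pos += n
        elif op in "DN":
            pos += n
    return blocks


def _equal_best_placements(
    ref: str, truth: SimTruth, start: int, cigar: Sequence[tuple[str, int]]
) -> list[int]:
    """All genome starts where the read's reference footprint is identical."""
    blocks = _footprint_blocks(start, cigar)
    end = blocks[-1][1]
    placements = [start]
    for fam in truth.families:
        for cs, ce in fam.copies:
            if start < ce and end > cs:  # read touches this copy
                for os_, oe in fam.copies:
                    if (os_, oe) == (cs, ce):
                        continue
                    delta = os_ - cs
                    cand = start + delta
                    if cand < 0 or end + delta > len(ref):
                        continue
                    if all(
                        ref[bs + delta : be + delta] == ref[bs:be]
                        for bs, be in blocks
                    ):
                        placements.append(cand)
                break  # a read belongs to at most one copy of a family
    return sorted(set(placements))


# ---------------------------------------------------------------------------
# truth-level expectations


def expected_dark_mapq_intervals(
    genome: GenomeSequence, truth: SimTruth
) -> list[tuple[int, int]]:
    """Positions where *every* covering read-length window is ambiguous.

    This is the conservative dark-by-MAPQ truth: any read overlapping
    such a position multi-maps, so close to 100% of its aligned reads
    carry MAPQ 0.
    """
    ref = genome[truth.contig]
    L = truth.read_length
    out: list[tuple[int, int]] = []
    for fam in truth.families:
        for cs, ce in fam.copies:
            w_lo = max(0, cs - L + 1)
            w_hi = min(ce - 1, len(ref) - L)
            amb = {
                w: len(_equal_best_placements(ref, truth, w, [("M", L)])) > 1
                for w in range(w_lo, w_hi + 1)
            }
            dark = []
            for p in range(cs, ce):
                lo = max(0, p - L + 1)
                hi = min(p, len(ref) - L)
                if hi < lo:
                    continue
                if all(amb.get(w, False) for w in range(lo, hi + 1)):
                    dark.append(p)
            # merge into runs
            run_start = None
            prev = None
            for p in dark:
                if run_start is None:
                    run_start = p
                elif p != prev + 1:
                    out.append((run_start, prev + 1))
                    run_start = p
                prev = p
            if run_start is not None:
                out.append((run_start, prev + 1))
    return out
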