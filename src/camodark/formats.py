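"""Standard-format I/O and the alignment-record contract.

All internal coordinates are 0-based half-open.  GTF input (1-based
inclusive) is converted on load; VCF output converts back to 1-based.
BED output follows two dialects: ``dark`` for dark-region intervals and
``camo`` for camouflaged-region sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam

__all__ = [
    "AlignedRead",
    "GenomeSequence",
    "TranscriptRecord",
    "read_alignments",
    "load_gene_models",
    "write_bed",
    "parse_bed",
    "write_vcf",
    "write_sam",
    "write_fasta",
    "read_fasta",
]

# CIGAR ops that consume the query sequence / the reference
_QUERY_OPS = frozenset("M=XIS")
_REF_OPS = frozenset("M=XDN")


@dataclass
class AlignedRead:
    """A single aligned short read (SAM semantics, 0-based start)."""

    name: str
    contig: str
    start: int
    mapq: int
    cigar: list[tuple[str, int]]
    sequence: str
    base_quals: Optional[list[int]] = None
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for read {self.name}")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"MAPQ {self.mapq} out of [0, 60] for read {self.name}")
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS and op != "H")
        if self.sequence and qlen != len(self.sequence):
            raise ValueError(
                f"CIGAR consumes {qlen} query bases but sequence has "
                f"{len(self.sequence)} for read {self.name}"
            )

    @property
    def end(self) -> int:
        """Half-open end of the reference footprint."""
        return self.start + sum(n for op, n in self.cigar if op in _REF_OPS)

    def reference_blocks(self) -> Iterator[tuple[int, int, int]]:
        """Yield (ref_start, ref_end, query_offset) for each aligned block.

        Deletion/skip (D/N) stretches are not yielded: a read contributes
        no aligned base at positions it spans with a gap.
        """
        rpos, qpos = self.start, 0
        for op, n in self.cigar:
            if op in "M=X":
                yield rpos, rpos + n, qpos
                rpos += n
                qpos += n
            elif op in "DN":
                rpos += n
            elif op in "IS":
                qpos += n
            # H consumes nothing

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and self.end > start


@dataclass
class GenomeSequence:
    """A reference genome held in memory, with mask bookkeeping.

    Masking replaces intervals with ``N`` without changing contig
    lengths, mirroring how a reference is prepared before realignment.
    """

    contigs: dict[str, str]
    masked: list[tuple[str, int, int]] = field(default_factory=list)

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def mask(self, contig: str, start: int, end: int) -> None:
        seq = self.contigs[contig]
        if not 0 <= start <= end <= len(seq):
            raise ValueError(f"mask interval [{start},{end}) outside {contig}")
        self.contigs[contig] = seq[:start] + "N" * (end - start) + seq[end:]
        self.masked.append((contig, start, end))

    def copy(self) -> "GenomeSequence":
        return GenomeSequence(dict(self.contigs), list(self.masked))


@dataclass
class TranscriptRecord:
    """One transcript with its exon/CDS/UTR features (0-based half-open)."""

    gene_id: str
    gene_symbol: str
    biotype: str
    transcript_id: str
    contig: str
    strand: str
    features: list[tuple[str, tuple[int, int]]]

    @property
    def span(self) -> tuple[int, int]:
        starts = [iv[0] for _, iv in self.features]
        ends = [iv[1] for _, iv in self.features]
        return min(starts), max(ends)


def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    cigar = [(op, n) for op, n in zip_cigar(rec)]
    return AlignedRead(
        name=rec.query_name or "",
        contig=rec.reference_name or "",
        start=rec.reference_start,
        mapq=min(rec.mapping_quality, 60),
        cigar=cigar,
        sequence=rec.query_sequence or "",
        base_quals=list(rec.query_qualities) if rec.query_qualities is not None else None,
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        is_duplicate=rec.is_duplicate,
    )


_CIGAR_CODES = "MIDNSHP=X"


def zip_cigar(rec: pysam.AlignedSegment) -> Iterator[tuple[str, int]]:
    for code, n in rec.cigartuples or []:
        yield _CIGAR_CODES[code], n


def read_alignments(
    path: str | Path,
    region: Optional[tuple[str, int, int]] = None,
    *,
    include_duplicates: bool = False,
    include_secondary: bool = False,
) -> Iterator[AlignedRead]:
    """Iterate primary, non-supplementary alignments from a SAM/BAM file.

    ``region`` is a (contig, start, end) half-open triple; region queries
    require an index for BAM.  Duplicate-flagged reads are skipped unless
    ``include_duplicates`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            if region is not None:
                contig, start, end = region
                it = fh.fetch(contig, start, end)
            else:
                it = fh.fetch(until_eof=True)
            for rec in it:
                if rec.is_unmapped:
                    continue
                if rec.is_secondary and not include_secondary:
                    continue
                if rec.is_supplementary:
                    continue
                if rec.is_duplicate and not include_duplicates:
                    continue
                try:
                    yield _from_pysam(rec)
                except ValueError as exc:
                    raise ValueError(f"malformed record {rec.query_name!r}: {exc}") from exc
    finally:
        pysam.set_verbosity(save)


_FEATURE_KINDS = {
    "exon": "exon",
    "CDS": "CDS",
    "five_prime_utr": "five_prime_utr",
    "three_prime_utr": "three_prime_utr",
}


def load_gene_models(path_gtf: str | Path) -> list[TranscriptRecord]:
    """Load transcript models from an Ensembl-dialect GTF.

    Records missing mandatory attributes (gene_id, transcript_id) are
    rejected with a warning.  Coordinates become 0-based half-open.
    """
    import gffutils

    path_gtf = Path(path_gtf)
    if not path_gtf.exists():
        raise FileNotFoundError(path_gtf)
    db = gffutils.create_db(
        str(path_gtf),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records: dict[str, TranscriptRecord] = {}
    n_rejected = 0
    for feat in db.all_features():
        kind = _FEATURE_KINDS.get(feat.featuretype)
        if kind is None:
            continue
        try:
            gene_id = feat.attributes["gene_id"][0]
            transcript_id = feat.attributes["transcript_id"][0]
        except KeyError:
            n_rejected += 1
            continue
        symbol = feat.attributes.get("gene_name", [gene_id])[0]
        biotype = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
        iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        rec = records.get(transcript_id)
        if rec is None:
            rec = TranscriptRecord(
                gene_id=gene_id,
                gene_symbol=symbol,
                biotype=biotype,
                transcript_id=transcript_id,
                contig=feat.seqid,
                strand=feat.strand,
                features=[],
            )
            records[transcript_id] = rec
        rec.features.append((kind, iv))
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} GTF records lacking mandatory attributes")
    return [r for r in records.values() if r.features]


_BED_DIALECTS = {
    "dark": ("chrom", "start", "end", "class", "mean_depth", "pct_low_mapq"),
    "camo": (
        "chrom",
        "start",
        "end",
        "set_id",
        "region_index",
        "repeat_count",
        "ploidy",
        "is_representative",
    ),
}


def write_bed(
    records: Sequence[tuple],
    path: str | Path,
    dialect: str,
    header: Optional[Sequence[str]] = None,
) -> None:
    """Write BED rows of the given dialect (``dark`` or ``camo``).

    ``records`` are tuples matching the dialect's columns, sorted by
    contig then start.  Optional ``header`` lines are written as
    ``#``-prefixed comments.
    """
    if dialect not in _BED_DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    cols = _BED_DIALECTS[dialect]
    prev: Optional[tuple[str, int]] = None
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        for rec in records:
            if len(rec) != len(cols):
                raise ValueError(
                    f"{dialect} dialect expects {len(cols)} columns, got {len(rec)}"
                )
            key = (str(rec[0]), int(rec[1]))
            if prev is not None and key < prev:
                raise ValueError("BED records must be sorted by contig then start")
            prev = key
            fh.write("\t".join(str(x) for x in rec) + "\n")


def parse_bed(path: str | Path, dialect: str) -> list[tuple]:
    """Parse a BED file written by :func:`write_bed` (round-trip inverse)."""
    if dialect not in _BED_DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    out: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            conv: list = []
            for val in parts:
                try:
                    conv.append(int(val))
                except ValueError:
                    try:
                        conv.append(float(val))
                    except ValueError:
                        conv.append(val)
            out.append(tuple(conv))
    return out


def write_vcf(
    variants: Sequence,
    reference: GenomeSequence,
    ploidy_map: dict[str, int],
    path: str | Path,
    sample: str = "SAMPLE",
    header_extra: Optional[Sequence[str]] = None,
) -> None:
    """Write a minimal VCF 4.2 with ploidy-many GT alleles.

    ``variants`` carry attributes contig, pos (0-based), ref_allele,
    alt_allele, alt_count, depth, qual, qd, filters and set_id;
    ``ploidy_map`` maps set_id to the genotype ploidy.  Hom-ref records
    (alt_count == 0) are not emitted.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in header_extra or []:
            fh.write(f"##{line}\n")
        for contig, seq in reference.contigs.items():
            fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in variants:
            ploidy = ploidy_map.get(getattr(v, "set_id", ""), 2)
            k = v.alt_count
            if k == 0:
                continue
            if k > ploidy:
                raise ValueError(
                    f"genotype allele count {k} exceeds ploidy {ploidy} at "
                    f"{v.contig}:{v.pos}"
                )
            gt = "/".join(["0"] * (ploidy - k) + ["1"] * k)
            filt = ";".join(sorted(v.filters)) if v.filters else "PASS"
            fh.write(
                f"{v.contig}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}\t"
                f"{v.qual:.2f}\t{filt}\tDP={v.depth};QD={v.qd:.2f}\tGT\t{gt}\n"
            )


def write_sam(
    reads: Iterable[AlignedRead], genome: GenomeSequence, path: str | Path
) -> None:
    """Write reads as plain-text SAM against the given genome's contigs."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": contig, "LN": len(seq)} for contig, seq in genome.contigs.items()
        ],
    }
    tid = {contig: i for i, contig in enumerate(genome.contigs)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for read in sorted(reads, key=lambda r: (tid[r.contig], r.start)):
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = read.name
            seg.reference_id = tid[read.contig]
            seg.reference_start = read.start
            seg.mapping_quality = read.mapq
            seg.cigarstring = "".join(f"{n}{op}" for op, n in read.cigar)
            seg.query_sequence = read.sequence
            if read.base_quals is not None:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.base_quals)
                )
            flag = 0
            if read.is_secondary:
                flag |= 0x100
            if read.is_duplicate:
                flag |= 0x400
            if read.is_supplementary:
                flag |= 0x800
            seg.flag = flag
            fh.write(seg)


def write_gtf(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts as Ensembl-dialect GTF (1-based inclusive)."""
    lines: list[tuple[str, int, str]] = []
    seen_genes: set[str] = set()
    for t in transcripts:
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_name "{t.gene_symbol}"; gene_biotype "{t.biotype}";'
        )
        gene_attrs = (
            f'gene_id "{t.gene_id}"; gene_name "{t.gene_symbol}"; '
            f'gene_biotype "{t.biotype}";'
        )
        span = t.span
        if t.gene_id not in seen_genes:
            seen_genes.add(t.gene_id)
            lines.append(
                (
                    t.contig,
                    span[0],
                    f"{t.contig}\tsim\tgene\t{span[0] + 1}\t{span[1]}\t.\t{t.strand}\t.\t{gene_attrs}",
                )
            )
        lines.append(
            (
                t.contig,
                span[0],
                f"{t.contig}\tsim\ttranscript\t{span[0] + 1}\t{span[1]}\t.\t{t.strand}\t.\t{attrs}",
            )
        )
        for kind, (s, e) in t.features:
            lines.append(
                (
                    t.contig,
                    s,
                    f"{t.contig}\tsim\t{kind}\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}",
                )
            )
    lines.sort(key=lambda x: (x[0], x[1]))
    with open(path, "w") as fh:
        for _, _, line in lines:
            fh.write(line + "\n")


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.contigs.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> GenomeSequence:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return GenomeSequence({name: str(fa[name][:]) for name in fa.keys()})
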