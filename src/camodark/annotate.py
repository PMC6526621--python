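"""Gene-level annotation of dark regions and summary statistics.

Transcript models are flattened to one element map per gene (each base
labelled CDS > UTR5/UTR3 > ncRNA exon > intron, taking the highest-
precedence label across transcripts).  Dark regions are intersected
with the maps and split at every element boundary, so each piece lies
in exactly one element of one gene; pieces conserve total overlap
length.  From the pieces we compute per-gene percent-dark statistics,
the AUC technology-comparison ratio (sum over genes of percent-dark,
relative to a reference technology), and a permutation-based disease
enrichment score, round(-10*log10(empirical p)).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats import TranscriptRecord
from .scan import DarkRegion

__all__ = [
    "GeneModel",
    "ElementDarkRecord",
    "GeneDarkStats",
    "flatten_gene_models",
    "intersect_and_split",
    "gene_dark_stats",
    "auc_comparison",
    "disease_enrichment",
]

# label codes, higher = higher precedence
_INTRON, _EXON_PC, _NC_EXON, _UTR3, _UTR5, _CDS = 0, 1, 2, 3, 4, 5
_KIND_OF_CODE = {
    _INTRON: "intron",
    _NC_EXON: "ncRNA_exon",
    _UTR3: "UTR3",
    _UTR5: "UTR5",
    _CDS: "CDS",
}
_CODING_BIOTYPES = {"protein_coding"}


@dataclass
class GeneModel:
    """A gene flattened to disjoint labelled elements partitioning its span."""

    gene_id: str
    symbol: str
    biotype: str
    contig: str
    strand: str
    span: tuple[int, int]
    elements: list[tuple[str, tuple[int, int]]]
    n_unresolved_utr: int = 0  # exonic coding-gene bases defaulted to UTR5

    def element_bases(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for kind, (s, e) in self.elements:
            out[kind] += e - s
        return dict(out)


@dataclass
class ElementDarkRecord:
    gene_id: str
    kind: str
    interval: tuple[int, int]
    klass: str
    multi_gene: bool = False

    @property
    def dark_bases(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class GeneDarkStats:
    gene_id: str
    symbol: str
    biotype: str
    pct_dark_body: float
    pct_dark_CDS: Optional[float]
    pct_dark_intron: Optional[float]
    pct_dark_exon: Optional[float]
    counts_by_klass: dict[str, int] = field(default_factory=dict)

    @property
    def completely_dark(self) -> bool:
        return self.pct_dark_body >= 100.0


def flatten_gene_models(transcripts: Sequence[TranscriptRecord]) -> list[GeneModel]:
    """Flatten transcript features to per-gene element maps.

    All transcripts of a gene must lie on one contig and strand.  Bases
    covered only by the exon feature of a coding gene (no CDS/UTR
    sub-feature in any transcript) cannot be resolved to a UTR side and
    are counted as UTR5, tallied in ``n_unresolved_utr``.
    """
    by_gene: dict[str, list[TranscriptRecord]] = defaultdict(list)
    for t in transcripts:
        by_gene[t.gene_id].append(t)
    models: list[GeneModel] = []
    for gene_id, txs in by_gene.items():
        contigs = {t.contig for t in txs}
        strands = {t.strand for t in txs}
        if len(contigs) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gene_id} spans multiple contigs/strands")
        biotype = txs[0].biotype
        coding = biotype in _CODING_BIOTYPES
        span_start = min(t.span[0] for t in txs)
        span_end = max(t.span[1] for t in txs)
        labels = np.zeros(span_end - span_start, dtype=np.int8)  # intron default
        unresolved = np.zeros(span_end - span_start, dtype=bool)
        for t in txs:
            for kind, (s, e) in t.features:
                lo, hi = s - span_start, e - span_start
                if kind == "exon":
                    code = _EXON_PC if coding else _NC_EXON
                elif kind == "CDS":
                    code = _CDS
                elif kind == "five_prime_utr":
                    code = _UTR5
                elif kind == "three_prime_utr":
                    code = _UTR3
                else:
                    continue
                np.maximum(labels[lo:hi], code, out=labels[lo:hi])
        if coding:
            mask = labels == _EXON_PC
            unresolved |= mask
            labels[mask] = _UTR5
        else:
            labels[labels == _EXON_PC] = _NC_EXON
        elements: list[tuple[str, tuple[int, int]]] = []
        run_start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[run_start]:
                kind = _KIND_OF_CODE[int(labels[run_start])]
                elements.append(
                    (kind, (span_start + run_start, span_start + i))
                )
                run_start = i
        models.append(
            GeneModel(
                gene_id=gene_id,
                symbol=txs[0].gene_symbol,
                biotype=biotype,
                contig=txs[0].contig,
                strand=txs[0].strand,
                span=(span_start, span_end),
                elements=elements,
                n_unresolved_utr=int(unresolved.sum()),
            )
        )
    models.sort(key=lambda g: (g.contig, g.span[0]))
    return models


def intersect_and_split(
    dark_regions: Sequence[DarkRegion],
    gene_models: Sequence[GeneModel],
) -> tuple[list[ElementDarkRecord], list[tuple[str, int, int]]]:
    """Clip dark regions to genes and split at element boundaries.

    Returns (records, intergenic): one record per (gene, element piece);
    a region overlapping several genes contributes a piece to each
    (``multi_gene`` flagged).  Dark stretches outside every gene span
    are returned as intergenic intervals.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gi, g in enumerate(gene_models):
        if g.span[1] > g.span[0]:
            trees[g.contig].addi(g.span[0], g.span[1], gi)
    records: list[ElementDarkRecord] = []
    intergenic: list[tuple[str, int, int]] = []
    for region in dark_regions:
        overlaps = sorted(
            trees[region.contig].overlap(region.start, region.end),
            key=lambda iv: iv.data,
        )
        multi = len(overlaps) > 1
        covered: list[tuple[int, int]] = []
        for iv in overlaps:
            gene = gene_models[iv.data]
            clip_s = max(region.start, gene.span[0])
            clip_e = min(region.end, gene.span[1])
            covered.append((clip_s, clip_e))
            for kind, (es, ee) in gene.elements:
                ps, pe = max(clip_s, es), min(clip_e, ee)
                if ps < pe:
                    records.append(
                        ElementDarkRecord(
                            gene_id=gene.gene_id,
                            kind=kind,
                            interval=(ps, pe),
                            klass=region.klass,
                            multi_gene=multi,
                        )
                    )
        # subtract gene-covered parts to get intergenic leftovers
        cursor = region.start
        for cs, ce in sorted(covered):
            if cs > cursor:
                intergenic.append((region.contig, cursor, cs))
            cursor = max(cursor, ce)
        if cursor < region.end:
            intergenic.append((region.contig, cursor, region.end))
    return records, intergenic


def gene_dark_stats(
    records: Sequence[ElementDarkRecord],
    gene_models: Sequence[GeneModel],
) -> list[GeneDarkStats]:
    """Per-gene percent-dark statistics from split element records.

    Percentages are 100 * dark bases / category bases; a category absent
    from the gene (e.g. CDS of a pseudogene) yields None.  Overlapping
    dark pieces within a gene are unioned per category so no base is
    counted twice.
    """
    by_gene: dict[str, list[ElementDarkRecord]] = defaultdict(list)
    for r in records:
        by_gene[r.gene_id].append(r)
    out: list[GeneDarkStats] = []
    exon_kinds = {"CDS", "UTR5", "UTR3", "ncRNA_exon"}
    for g in gene_models:
        recs = by_gene.get(g.gene_id, [])
        cat_bases = g.element_bases()
        body_len = g.span[1] - g.span[0]
        cds_len = cat_bases.get("CDS", 0)
        intron_len = cat_bases.get("intron", 0)
        exon_len = sum(cat_bases.get(k, 0) for k in exon_kinds)

        def dark_len(pred) -> int:
            ivs = sorted(r.interval for r in recs if pred(r))
            total, cursor = 0, -1
            for s, e in ivs:
                s = max(s, cursor)
                if e > s:
                    total += e - s
                    cursor = e
                else:
                    cursor = max(cursor, e)
            return total

        dark_body = dark_len(lambda r: True)
        dark_cds = dark_len(lambda r: r.kind == "CDS")
        dark_intron = dark_len(lambda r: r.kind == "intron")
        dark_exon = dark_len(lambda r: r.kind in exon_kinds)
        counts: dict[str, int] = defaultdict(int)
        for r in recs:
            counts[r.klass] += 1
        out.append(
            GeneDarkStats(
                gene_id=g.gene_id,
                symbol=g.symbol,
                biotype=g.biotype,
                pct_dark_body=100.0 * dark_body / body_len if body_len else 0.0,
                pct_dark_CDS=100.0 * dark_cds / cds_len if cds_len else None,
                pct_dark_intron=100.0 * dark_intron / intron_len if intron_len else None,
                pct_dark_exon=100.0 * dark_exon / exon_len if exon_len else None,
                counts_by_klass=dict(counts),
            )
        )
    return out


def auc_comparison(
    stats_reference: Sequence[GeneDarkStats],
    stats_other: Sequence[GeneDarkStats],
    attr: str = "pct_dark_body",
) -> float:
    """Ratio of summed per-gene percent-dark, other over reference.

    Both inputs must cover the same gene universe.  The reference
    technology's own ratio is 1.0 by construction.
    """
    ref = {s.gene_id: getattr(s, attr) or 0.0 for s in stats_reference}
    other = {s.gene_id: getattr(s, attr) or 0.0 for s in stats_other}
    if not ref:
        raise ValueError("empty gene set")
    if set(ref) != set(other):
        raise ValueError("gene universes differ")
    denom = sum(ref.values())
    if denom == 0:
        raise ValueError("reference has no dark genes; AUC ratio undefined")
    return sum(other.values()) / denom


def disease_enrichment(
    dark_gene_set: Sequence[str],
    gene_disease_table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Permutation enrichment of dark genes per disease.

    ``gene_disease_table`` has columns ``gene`` and ``disease``.  For
    each disease, the observed count of dark genes annotated to it is
    compared against ``n_perm`` random draws of equally many genes from
    the table's gene universe; the empirical p-value uses the +1
    pseudo-count, p = (1 + #{perm >= obs}) / (n_perm + 1), and the score
    is round(-10*log10(p)).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if gene_disease_table.empty:
        raise ValueError("empty gene-disease table")
    if rng is None:
        rng = np.random.default_rng(seed)
    table = gene_disease_table[["gene", "disease"]].drop_duplicates()
    genes = table["gene"].unique()
    universe = pd.Index(genes)
    dark = [g for g in set(dark_gene_set) if g in set(universe)]
    if not dark:
        raise ValueError("no dark genes in the table's gene universe")
    diseases = table["disease"].unique()
    indicator = (
        pd.crosstab(table["gene"], table["disease"])
        .reindex(index=universe, columns=diseases, fill_value=0)
        .to_numpy()
        .astype(np.int32)
    )
    dark_idx = universe.get_indexer(pd.Index(sorted(dark)))
    observed = indicator[dark_idx].sum(axis=0)
    n_draw = len(dark_idx)
    ge_counts = np.zeros(len(diseases), dtype=np.int64)
    for _ in range(n_perm):
        idx = rng.choice(len(universe), size=n_draw, replace=False)
        counts = indicator[idx].sum(axis=0)
        ge_counts += counts >= observed
    pvals = (1.0 + ge_counts) / (n_perm + 1.0)
    scores = np.rint(-10.0 * np.log10(pvals)).astype(int)
    return pd.DataFrame(
        {
            "disease": diseases,
            "observed": observed,
            "p_value": pvals,
            "score": scores,
        }
    ).sort_values("score", ascending=False, ignore_index=True)
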