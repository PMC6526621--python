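"""Camouflaged-region discovery, set construction and mask planning.

Dark-by-MAPQ regions arise when a segment has a near-identical copy
elsewhere in the genome.  This module finds those partners with an
exact-k-mer-seeded, affine-gapped search, groups mutually similar
regions (>= 98% identity over alignment columns, gap columns included)
into *camo sets* by transitive closure, and plans the reference masking
used for rescue: every set keeps exactly one unmasked representative
(the left-most region on the lowest-ordered contig) to which all pooled
reads will be realigned.  The calling ploidy for a set is twice its
repeat count — hexaploid for three copies.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .alignment import Alignment, ScoringScheme, align, percent_identity
from .formats import GenomeSequence
from .scan import DarkRegion, DarkScanConfig

__all__ = [
    "Interval",
    "SimilarityHit",
    "CamoSet",
    "MaskPlan",
    "KmerIndex",
    "find_similar_regions",
    "build_camo_sets",
    "repeat_count_histogram",
    "plan_masking",
]

Interval = tuple[str, int, int]  # contig, start, end (half-open)


@dataclass
class SimilarityHit:
    query: Interval
    subject: Interval
    pct_identity: float
    aligned_length: int


@dataclass
class CamoSet:
    set_id: str
    regions: list[Interval]  # ordered; index 0 is the representative
    intra_gene: bool = False

    @property
    def representative(self) -> Interval:
        return self.regions[0]

    @property
    def repeat_count(self) -> int:
        return len(self.regions)

    @property
    def ploidy(self) -> int:
        return 2 * self.repeat_count


@dataclass
class MaskPlan:
    """Per-set representative and the intervals masked to N."""

    plans: dict[str, tuple[Interval, list[Interval]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            sid: {"representative": list(rep), "masked": [list(iv) for iv in masked]}
            for sid, (rep, masked) in self.plans.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaskPlan":
        plans = {
            sid: (
                tuple(v["representative"]),
                [tuple(iv) for iv in v["masked"]],
            )
            for sid, v in d.items()
        }
        return cls(plans)


class KmerIndex:
    """Exact k-mer positions over a genome (seeding for similarity search)."""

    def __init__(self, genome: GenomeSequence, k: int = 11):
        self.k = k
        self.index: dict[str, dict[str, list[int]]] = {}
        for contig, seq in genome.contigs.items():
            table: dict[str, list[int]] = defaultdict(list)
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    table[kmer].append(i)
            self.index[contig] = dict(table)

    def seeds(self, query: str, contig: str) -> list[tuple[int, int]]:
        """(query_offset, genome_pos) seed matches on one contig."""
        table = self.index.get(contig, {})
        out = []
        for qo in range(len(query) - self.k + 1):
            for gp in table.get(query[qo : qo + self.k], ()):
                out.append((qo, gp))
        return out


def find_similar_regions(
    query: Interval,
    genome: GenomeSequence,
    min_identity: float = 98.0,
    *,
    index: Optional[KmerIndex] = None,
    scoring: ScoringScheme = ScoringScheme(),
    min_aligned_frac: float = 0.5,
    diag_slack: int = 20,
    pad: int = 30,
) -> list[SimilarityHit]:
    """Find genomic regions highly similar to ``query``.

    Seeds exact k-mers, clusters them by diagonal, runs a gapped local
    alignment on each candidate window, and keeps hits whose identity
    over alignment columns is >= ``min_identity`` and that cover at
    least ``min_aligned_frac`` of the query (so incidental seed
    collisions do not qualify).  The trivial self-hit is removed.
    """
    contig, qstart, qend = query
    if qend - qstart < 20:
        raise ValueError("query must be >= 20 bases")
    qseq = genome.fetch(contig, qstart, qend)
    if set(qseq) <= {"N"}:
        raise ValueError("query contains only N")
    if index is None:
        index = KmerIndex(genome)
    hits: list[SimilarityHit] = []
    for subj_contig in genome.contigs:
        seeds = index.seeds(qseq, subj_contig)
        windows = _cluster_windows(
            seeds, len(qseq), genome.length(subj_contig), diag_slack, pad
        )
        for wstart, wend in windows:
            if subj_contig == contig and wstart < qend and wend > qstart:
                # candidate overlapping the query itself: the optimal local
                # alignment here is the trivial self-hit; skip unless the
                # window extends well beyond the query (tandem partner)
                if wstart >= qstart - pad and wend <= qend + pad:
                    continue
            wseq = genome.fetch(subj_contig, wstart, wend)
            aln = align(qseq, wseq, scoring, mode="local")
            if aln.n_columns == 0:
                continue
            subject = (
                subj_contig,
                wstart + aln.subject_start,
                wstart + aln.subject_end,
            )
            if subj_contig == contig and _jaccard(subject[1:], (qstart, qend)) > 0.5:
                continue  # self-hit
            ident = percent_identity(aln)
            qcov = (aln.query_end - aln.query_start) / len(qseq)
            if ident >= min_identity and qcov >= min_aligned_frac:
                hits.append(
                    SimilarityHit(
                        query=query,
                        subject=subject,
                        pct_identity=ident,
                        aligned_length=aln.n_columns,
                    )
                )
    hits.sort(key=lambda h: -h.pct_identity)
    return _dedupe_hits(hits)


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def _cluster_windows(
    seeds: Sequence[tuple[int, int]],
    qlen: int,
    contig_len: int,
    diag_slack: int,
    pad: int,
) -> list[tuple[int, int]]:
    if not seeds:
        return []
    diags = sorted(gp - qo for qo, gp in seeds)
    clusters: list[list[int]] = [[diags[0]]]
    for d in diags[1:]:
        if d - clusters[-1][-1] <= diag_slack:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    windows = []
    for cl in clusters:
        start = max(0, cl[0] - pad)
        end = min(contig_len, cl[-1] + qlen + pad)
        if end - start >= 20:
            windows.append((start, end))
    return windows


def _dedupe_hits(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    kept: list[SimilarityHit] = []
    for h in hits:
        if any(
            k.subject[0] == h.subject[0]
            and _jaccard(k.subject[1:], h.subject[1:]) > 0.5
            for k in kept
        ):
            continue
        kept.append(h)
    return kept


def camo_candidate_regions(
    dark_mapq_regions: Sequence[DarkRegion],
    gene_models: Sequence,
    kinds: frozenset[str] = frozenset({"CDS"}),
) -> list[DarkRegion]:
    """Expand dark-by-MAPQ regions to the gene elements they fall in.

    Rescue operates on whole camouflaged CDS exons: a dark core inside
    an exon marks the entire exon as the camouflaged unit (the exon is
    what gets masked and what reads are pooled over).  Elements of the
    requested kinds overlapping any dark-by-MAPQ region are returned as
    camo candidate regions; elements are deduplicated.
    """
    out: list[DarkRegion] = []
    seen: set[Interval] = set()
    for g in gene_models:
        for kind, (es, ee) in g.elements:
            if kind not in kinds:
                continue
            iv = (g.contig, es, ee)
            if iv in seen:
                continue
            for r in dark_mapq_regions:
                if r.contig == g.contig and r.start < ee and r.end > es:
                    seen.add(iv)
                    out.append(
                        DarkRegion(
                            contig=g.contig,
                            start=es,
                            end=ee,
                            klass=r.klass,
                            mean_depth=r.mean_depth,
                            mean_low_mapq_pct=r.mean_low_mapq_pct,
                        )
                    )
                    break
    out.sort(key=lambda r: (r.contig, r.start))
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_camo_sets(
    dark_mapq_regions: Sequence[DarkRegion],
    hits: Mapping[int, Sequence[SimilarityHit]],
    low_mapq_mass: Optional[Mapping[str, np.ndarray]] = None,
    config: DarkScanConfig = DarkScanConfig(),
    gene_spans: Optional[Sequence[Interval]] = None,
) -> list[CamoSet]:
    """Group dark-by-MAPQ regions into camo sets.

    ``hits`` maps a region's index in ``dark_mapq_regions`` to its
    similarity hits.  Two regions join the same set when a qualifying
    hit links them *and* the partner carries a mean low-MAPQ mass of at
    least ``config.camo_mass_min_pct`` percent (skipped when
    ``low_mapq_mass``, a contig -> per-position fraction array, is not
    given).  Sets are the connected components of this graph; only sets
    with >= 2 regions are camouflaged.  ``gene_spans`` lets sets whose
    regions all fall inside one gene be flagged ``intra_gene``.
    """
    regions = list(dark_mapq_regions)
    order = sorted(range(len(regions)), key=lambda i: (regions[i].contig, regions[i].start))
    uf = _UnionFind(len(regions))
    for qi, region_hits in hits.items():
        for hit in region_hits:
            pj = _match_region(hit.subject, regions)
            if pj is None or pj == qi:
                continue
            if low_mapq_mass is not None and not _mass_ok(
                hit.subject, low_mapq_mass, config.camo_mass_min_pct
            ):
                continue
            uf.union(qi, pj)
    comps: dict[int, list[int]] = defaultdict(list)
    for i in order:
        comps[uf.find(i)].append(i)
    sets: list[CamoSet] = []
    n = 0
    for root in sorted(comps, key=lambda r: (regions[comps[r][0]].contig, regions[comps[r][0]].start)):
        members = comps[root]
        if len(members) < 2:
            continue
        n += 1
        ivs = [(regions[i].contig, regions[i].start, regions[i].end) for i in members]
        ivs.sort()
        intra = False
        if gene_spans is not None:
            intra = any(
                all(c == gc and s >= gs and e <= ge for c, s, e in ivs)
                for gc, gs, ge in gene_spans
            )
        sets.append(CamoSet(set_id=f"set_{n}", regions=ivs, intra_gene=intra))
    return sets


def _match_region(
    subject: Interval, regions: Sequence[DarkRegion], min_overlap: int = 10
) -> Optional[int]:
    best, best_ov = None, 0
    for i, r in enumerate(regions):
        if r.contig != subject[0]:
            continue
        ov = min(r.end, subject[2]) - max(r.start, subject[1])
        if ov >= min_overlap and ov > best_ov:
            best, best_ov = i, ov
    return best


def _mass_ok(
    subject: Interval, mass: Mapping[str, np.ndarray], min_pct: float
) -> bool:
    arr = mass.get(subject[0])
    if arr is None:
        return False
    frac = float(np.mean(arr[subject[1] : subject[2]]))
    return frac * 100.0 >= min_pct


def repeat_count_histogram(sets: Sequence[CamoSet]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for s in sets:
        hist[s.repeat_count] = hist.get(s.repeat_count, 0) + 1
    return dict(sorted(hist.items()))


def plan_masking(
    sets: Sequence[CamoSet], genome: GenomeSequence
) -> tuple[MaskPlan, GenomeSequence, list[tuple]]:
    """Mask every non-representative region; emit plan + camo BED rows.

    Sets with overlapping regions are merged before masking.  It is a
    hard error if another set's mask would cover a representative.
    """
    sets = _merge_overlapping_sets(sets)
    plan = MaskPlan()
    masked_genome = genome.copy()
    bed_rows: list[tuple] = []
    all_masks: list[Interval] = []
    for s in sets:
        rep = s.representative
        masked = s.regions[1:]
        plan.plans[s.set_id] = (rep, list(masked))
        all_masks.extend(masked)
        for idx, (contig, start, end) in enumerate(s.regions):
            bed_rows.append(
                (
                    contig,
                    start,
                    end,
                    s.set_id,
                    idx,
                    s.repeat_count,
                    s.ploidy,
                    int(idx == 0),
                )
            )
    for s in sets:
        rc, rs, re_ = s.representative
        for mc, ms, me in all_masks:
            if mc == rc and ms < re_ and me > rs:
                raise ValueError(
                    f"representative {s.set_id} {s.representative} overlapped by a mask"
                )
    for contig, start, end in all_masks:
        masked_genome.mask(contig, start, end)
    bed_rows.sort(key=lambda r: (r[0], r[1]))
    return plan, masked_genome, bed_rows


def _merge_overlapping_sets(sets: Sequence[CamoSet]) -> list[CamoSet]:
    sets = list(sets)
    uf = _UnionFind(len(sets))
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if any(
                a[0] == b[0] and a[1] < b[2] and b[1] < a[2]
                for a in sets[i].regions
                for b in sets[j].regions
            ):
                uf.union(i, j)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(sets)):
        groups[uf.find(i)].append(i)
    out: list[CamoSet] = []
    for gi, members in enumerate(sorted(groups.values(), key=lambda m: min(m)), 1):
        if len(members) == 1:
            s = sets[members[0]]
            out.append(CamoSet(f"set_{gi}", list(s.regions), s.intra_gene))
        else:
            ivs = sorted({iv for m in members for iv in sets[m].regions})
            intra = all(sets[m].intra_gene for m in members)
            out.append(CamoSet(f"set_{gi}", ivs, intra))
    return out
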