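"""Similarity search, camo-set construction, and mask planning."""

import networkx as nx
import numpy as np
import pytest

from camodark import (
    CamoSet,
    DarkRegion,
    DuplicationFamily,
    GenomeSequence,
    KmerIndex,
    SimSpec,
    build_camo_sets,
    find_similar_regions,
    plan_masking,
    repeat_count_histogram,
    simulate_genome,
)
from camodark.camo import SimilarityHit, camo_candidate_regions
from camodark.scan import DarkScanConfig


def _genome_with_copies(rng, n_copies=2, seg_len=300, mutate=0):
    """Random genome with duplicated segment; ``mutate`` substitutions per extra copy."""
    bases = list("ACGT")
    bg = "".join(rng.choice(bases, size=6000))
    seg = "".join(rng.choice(bases, size=seg_len))
    seq = list(bg)
    starts = [500 + i * 1500 for i in range(n_copies)]
    for i, s in enumerate(starts):
        copy = list(seg)
        if i > 0 and mutate:
            for off in rng.choice(np.arange(10, seg_len - 10), size=mutate, replace=False):
                copy[off] = bases[(bases.index(copy[off]) + 1) % 4]
        seq[s : s + seg_len] = copy
    return GenomeSequence({"chr1": "".join(seq)}), [(s, s + seg_len) for s in starts]


def _dark(start, end, contig="chr1"):
    return DarkRegion(contig, start, end, "dark_by_mapq", 35.0, 98.0)


class TestFindSimilarRegions:
    def test_verbatim_duplicate_found_at_full_identity(self, rng):
        genome, copies = _genome_with_copies(rng, 2)
        (hit,) = find_similar_regions(("chr1", *copies[0]), genome)
        assert hit.pct_identity == 100.0
        s, e = hit.subject[1], hit.subject[2]
        assert (s, e) == copies[1]

    def test_identity_cutoff_keeps_99_drops_97(self, rng):
        # 3 mismatches per 300 columns = 99.0%; 9 per 300 = 97.0%
        genome99, copies = _genome_with_copies(rng, 2, mutate=3)
        hits = find_similar_regions(("chr1", *copies[0]), genome99)
        assert len(hits) == 1 and hits[0].pct_identity == pytest.approx(99.0)
        genome97, copies = _genome_with_copies(rng, 2, mutate=9)
        assert find_similar_regions(("chr1", *copies[0]), genome97) == []

    def test_unique_sequence_has_no_hits(self, rng):
        genome, copies = _genome_with_copies(rng, 2)
        # a flank region between the copies is unique background
        assert find_similar_regions(("chr1", 900, 1100), genome) == []

    def test_all_n_query_rejected(self):
        genome = GenomeSequence({"chr1": "N" * 100 + "ACGT" * 100})
        with pytest.raises(ValueError, match="only N"):
            find_similar_regions(("chr1", 0, 50), genome)

    def test_short_query_rejected(self, rng):
        genome, copies = _genome_with_copies(rng, 2)
        with pytest.raises(ValueError, match=">= 20"):
            find_similar_regions(("chr1", 0, 10), genome)


class TestBuildCamoSets:
    def test_pair_makes_one_set_of_ploidy_four(self, rng):
        genome, copies = _genome_with_copies(rng, 2)
        regions = [_dark(*c) for c in copies]
        idx = KmerIndex(genome)
        hits = {
            i: find_similar_regions(("chr1", r.start, r.end), genome, index=idx)
            for i, r in enumerate(regions)
        }
        (s,) = build_camo_sets(regions, hits)
        assert s.repeat_count == 2 and s.ploidy == 4
        assert s.regions[0] == ("chr1", *copies[0])  # left-most representative

    def test_transitive_closure_links_a_b_c(self):
        # A~B and B~C qualify; A~C is absent: one set {A, B, C}
        regions = [_dark(0, 100), _dark(1000, 1100), _dark(2000, 2100)]
        mk = lambda q, s: SimilarityHit(("chr1", *q), ("chr1", *s), 99.0, 100)
        hits = {
            0: [mk((0, 100), (1000, 1100))],
            1: [mk((1000, 1100), (2000, 2100))],
        }
        (s,) = build_camo_sets(regions, hits)
        assert s.repeat_count == 3 and s.ploidy == 6  # hexaploid

    def test_partner_must_carry_camo_mass(self):
        regions = [_dark(0, 100), _dark(1000, 1100)]
        hits = {0: [SimilarityHit(("chr1", 0, 100), ("chr1", 1000, 1100), 99.0, 100)]}
        lo = {"chr1": np.full(3000, 0.2)}   # 20% low-MAPQ mass: below camo_mass
        hi = {"chr1": np.full(3000, 0.6)}   # 60%: qualifies
        assert build_camo_sets(regions, hits, lo) == []
        assert len(build_camo_sets(regions, hits, hi)) == 1

    def test_intra_gene_flag_from_gene_spans(self):
        regions = [_dark(100, 200), _dark(500, 600)]
        hits = {0: [SimilarityHit(("chr1", 100, 200), ("chr1", 500, 600), 100.0, 100)]}
        (s_in,) = build_camo_sets(regions, hits, gene_spans=[("chr1", 0, 1000)])
        (s_out,) = build_camo_sets(regions, hits, gene_spans=[("chr1", 0, 300)])
        assert s_in.intra_gene and not s_out.intra_gene

    def test_components_match_networkx_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 12))
            regions = [_dark(i * 1000, i * 1000 + 100) for i in range(n)]
            g = nx.Graph()
            g.add_nodes_from(range(n))
            hits = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.25:
                        g.add_edge(i, j)
                        hits.setdefault(i, []).append(
                            SimilarityHit(
                                ("chr1", i * 1000, i * 1000 + 100),
                                ("chr1", j * 1000, j * 1000 + 100),
                                99.5,
                                100,
                            )
                        )
            sets = build_camo_sets(regions, hits)
            expected = sorted(
                tuple(sorted(c)) for c in nx.connected_components(g) if len(c) > 1
            )
            got = sorted(
                tuple(sorted(r[1] // 1000 for r in s.regions)) for s in sets
            )
            assert got == expected


class TestRepeatHistogram:
    def test_counts_sets_by_size(self):
        sets = [
            CamoSet("a", [("chr1", 0, 10), ("chr1", 20, 30)]),
            CamoSet("b", [("chr1", 40, 50), ("chr1", 60, 70)]),
            CamoSet("c", [("chr1", 0, 9), ("chr1", 10, 19), ("chr1", 20, 29),
                          ("chr1", 30, 39), ("chr1", 40, 49)]),
        ]
        assert repeat_count_histogram(sets) == {2: 2, 5: 1}
        assert repeat_count_histogram([]) == {}

    def test_planted_five_copy_family(self):
        spec = SimSpec(
            genome_length=9000,
            families=(DuplicationFamily(copy_count=5, segment_length=200),),
            seed=2,
        )
        genome, _, truth = simulate_genome(spec)
        regions = [_dark(*c) for c in truth.families[0].copies]
        idx = KmerIndex(genome)
        hits = {
            i: find_similar_regions(("chr1", r.start, r.end), genome, index=idx)
            for i, r in enumerate(regions)
        }
        sets = build_camo_sets(regions, hits)
        assert repeat_count_histogram(sets) == {5: 1}


class TestPlanMasking:
    def _sets(self, rng):
        genome, copies = _genome_with_copies(rng, 3)
        regions = [_dark(*c) for c in copies]
        idx = KmerIndex(genome)
        hits = {
            i: find_similar_regions(("chr1", r.start, r.end), genome, index=idx)
            for i, r in enumerate(regions)
        }
        return genome, copies, build_camo_sets(regions, hits)

    def test_representative_untouched_others_masked(self, rng):
        genome, copies, sets = self._sets(rng)
        plan, masked, bed = plan_masking(sets, genome)
        rep = copies[0]
        assert masked.fetch("chr1", *rep) == genome.fetch("chr1", *rep)
        for s, e in copies[1:]:
            assert masked.fetch("chr1", s, e) == "N" * (e - s)
        assert masked.length("chr1") == genome.length("chr1")

    def test_camo_bed_rows_carry_hexaploid_ploidy(self, rng):
        genome, copies, sets = self._sets(rng)
        _, _, bed = plan_masking(sets, genome)
        assert len(bed) == 3
        assert all(row[6] == 6 for row in bed)
        assert [row[7] for row in bed] == [1, 0, 0]

    def test_masked_space_has_no_residual_hits(self, rng):
        genome, copies, sets = self._sets(rng)
        _, masked, _ = plan_masking(sets, genome)
        assert find_similar_regions(("chr1", *copies[0]), masked) == []

    def test_overlapping_sets_merged(self):
        genome = GenomeSequence({"chr1": "ACGT" * 1000})
        s1 = CamoSet("x", [("chr1", 0, 100), ("chr1", 500, 600)])
        s2 = CamoSet("y", [("chr1", 550, 650), ("chr1", 1000, 1100)])
        plan, masked, bed = plan_masking([s1, s2], genome)
        assert len(plan.plans) == 1
        (rep, masked_ivs) = next(iter(plan.plans.values()))
        assert rep == ("chr1", 0, 100)
        assert len(masked_ivs) == 3


def test_candidate_regions_snap_dark_cores_to_cds_exons(three_exon_data):
    from camodark.annotate import flatten_gene_models

    spec, genome, transcripts, truth, reads = three_exon_data
    gms = flatten_gene_models(transcripts)
    copies = truth.families[0].copies
    core = _dark(copies[1][0] + 120, copies[1][0] + 220)
    out = camo_candidate_regions([core], gms)
    assert [(r.start, r.end) for r in out] == [copies[1]]
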