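"""Gene flattening, dark-region splitting, and the summary statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from camodark import (
    DarkRegion,
    TranscriptRecord,
    auc_comparison,
    disease_enrichment,
    flatten_gene_models,
    gene_dark_stats,
    intersect_and_split,
)
from camodark.annotate import GeneModel


def _tx(gene="G1", tid="T1", biotype="protein_coding", feats=None, contig="chr1"):
    return TranscriptRecord(gene, gene, biotype, tid, contig, "+", feats or [])


def _dark(start, end, klass="dark_by_mapq", contig="chr1"):
    return DarkRegion(contig, start, end, klass, 30.0, 95.0)


class TestFlatten:
    def test_utr_cds_intron_labelling(self):
        tx = _tx(feats=[
            ("exon", (0, 10)), ("exon", (20, 30)),
            ("CDS", (5, 10)), ("CDS", (20, 25)),
            ("five_prime_utr", (0, 5)), ("three_prime_utr", (25, 30)),
        ])
        (gm,) = flatten_gene_models([tx])
        assert gm.elements == [
            ("UTR5", (0, 5)),
            ("CDS", (5, 10)),
            ("intron", (10, 20)),
            ("CDS", (20, 25)),
            ("UTR3", (25, 30)),
        ]
        assert sum(e - s for _, (s, e) in gm.elements) == gm.span[1] - gm.span[0]

    def test_cds_wins_over_intron_across_transcripts(self):
        t1 = _tx(tid="T1", feats=[("exon", (0, 30)), ("CDS", (10, 20)),
                                  ("five_prime_utr", (0, 10)), ("three_prime_utr", (20, 30))])
        t2 = _tx(tid="T2", feats=[("exon", (0, 5)), ("CDS", (0, 5)),
                                  ("exon", (25, 30)), ("CDS", (25, 30))])
        (gm,) = flatten_gene_models([t1, t2])
        kinds = dict((iv, k) for k, iv in gm.elements)
        # base 12 is CDS in T1 and intronic in T2 -> CDS
        assert any(k == "CDS" and s <= 12 < e for k, (s, e) in gm.elements)

    def test_pseudogene_exons_become_ncrna(self):
        tx = _tx(biotype="processed_pseudogene",
                 feats=[("exon", (0, 10)), ("exon", (30, 40))])
        (gm,) = flatten_gene_models([tx])
        assert [k for k, _ in gm.elements] == ["ncRNA_exon", "intron", "ncRNA_exon"]
        assert "CDS" not in {k for k, _ in gm.elements}

    def test_coding_exon_without_cds_or_utr_defaults_to_utr5_flagged(self):
        tx = _tx(feats=[("exon", (0, 10)), ("CDS", (0, 5))])
        (gm,) = flatten_gene_models([tx])
        assert ("UTR5", (5, 10)) in gm.elements
        assert gm.n_unresolved_utr == 5

    def test_multi_contig_gene_rejected(self):
        t1 = _tx(tid="T1", contig="chr1", feats=[("exon", (0, 10))])
        t2 = _tx(tid="T2", contig="chr2", feats=[("exon", (0, 10))])
        with pytest.raises(ValueError, match="multiple contigs"):
            flatten_gene_models([t1, t2])


class TestIntersectAndSplit:
    def _gene(self):
        tx = _tx(feats=[
            ("exon", (90, 110)), ("exon", (110, 130)),
            ("five_prime_utr", (90, 110)), ("CDS", (110, 130)),
        ])
        # force an intron-like structure: [90,110) UTR5, [110,130) CDS
        return flatten_gene_models([tx])

    def test_split_at_element_boundary_conserves_length(self):
        gms = self._gene()
        records, intergenic = intersect_and_split([_dark(95, 125)], gms)
        assert sorted((r.kind, r.dark_bases) for r in records) == [
            ("CDS", 15), ("UTR5", 15),
        ]
        assert intergenic == []

    def test_fully_intronic_region_yields_one_record(self):
        tx = _tx(feats=[("exon", (0, 10)), ("CDS", (0, 10)),
                        ("exon", (100, 110)), ("CDS", (100, 110))])
        gms = flatten_gene_models([tx])
        records, _ = intersect_and_split([_dark(30, 60)], gms)
        assert [(r.kind, r.dark_bases) for r in records] == [("intron", 30)]

    def test_region_overlapping_two_genes_counted_per_gene_and_flagged(self):
        t1 = _tx(gene="G1", tid="T1", feats=[("exon", (0, 100)), ("CDS", (0, 100))])
        t2 = _tx(gene="G2", tid="T2", feats=[("exon", (80, 200)), ("CDS", (80, 200))])
        gms = flatten_gene_models([t1, t2])
        records, _ = intersect_and_split([_dark(60, 120)], gms)
        assert {r.gene_id for r in records} == {"G1", "G2"}
        assert all(r.multi_gene for r in records)
        by_gene = {r.gene_id: r.dark_bases for r in records}
        assert by_gene == {"G1": 40, "G2": 40}

    def test_intergenic_leftovers_reported(self):
        tx = _tx(feats=[("exon", (100, 200)), ("CDS", (100, 200))])
        gms = flatten_gene_models([tx])
        records, intergenic = intersect_and_split([_dark(50, 250)], gms)
        assert sum(r.dark_bases for r in records) == 100
        assert intergenic == [("chr1", 50, 100), ("chr1", 200, 250)]

    def test_random_pairs_conserve_clipped_length(self, rng):
        for _ in range(300):
            # random gene: random element boundaries over a random span
            span_start = int(rng.integers(0, 500))
            n_elem = int(rng.integers(1, 6))
            bounds = np.sort(rng.integers(1, 400, size=n_elem - 1)) if n_elem > 1 else []
            edges = [0, *bounds.tolist(), 400] if n_elem > 1 else [0, 400]
            kinds = rng.choice(["CDS", "UTR5", "UTR3", "intron"], size=len(edges) - 1)
            elements = [
                (str(k), (span_start + a, span_start + b))
                for k, a, b in zip(kinds, edges[:-1], edges[1:])
                if b > a
            ]
            gm = GeneModel("G", "G", "protein_coding", "chr1", "+",
                           (span_start, span_start + 400), elements)
            ds = int(rng.integers(0, 900))
            de = ds + int(rng.integers(1, 300))
            records, intergenic = intersect_and_split([_dark(ds, de)], [gm])
            clipped = max(0, min(de, span_start + 400) - max(ds, span_start))
            assert sum(r.dark_bases for r in records) == clipped
            total = sum(r.dark_bases for r in records) + sum(e - s for _, s, e in intergenic)
            assert total == de - ds


class TestGeneDarkStats:
    def _gene_and_records(self, dark_intervals, gene_len=1000, cds=(400, 900)):
        tx = _tx(feats=[("exon", (0, gene_len)), ("CDS", cds),
                        ("five_prime_utr", (0, cds[0])), ("three_prime_utr", (cds[1], gene_len))])
        gms = flatten_gene_models([tx])
        regions = [_dark(s, e) for s, e in dark_intervals]
        records, _ = intersect_and_split(regions, gms)
        return gms, records

    def test_quarter_dark_gene(self):
        gms, records = self._gene_and_records([(0, 250)])
        (s,) = gene_dark_stats(records, gms)
        assert s.pct_dark_body == pytest.approx(25.0)
        assert not s.completely_dark

    def test_fully_dark_gene_flagged_complete(self):
        gms, records = self._gene_and_records([(0, 1000)])
        (s,) = gene_dark_stats(records, gms)
        assert s.pct_dark_body == pytest.approx(100.0)
        assert s.completely_dark

    def test_five_percent_cds_threshold(self):
        gms, records = self._gene_and_records([(400, 425)])  # 25 of 500 CDS nt
        (s,) = gene_dark_stats(records, gms)
        assert s.pct_dark_CDS == pytest.approx(5.0)
        assert s.pct_dark_CDS >= 5.0  # passes the reporting filter

    def test_zero_length_category_reported_absent(self):
        tx = _tx(biotype="lincRNA", feats=[("exon", (0, 100))])
        gms = flatten_gene_models([tx])
        records, _ = intersect_and_split([_dark(0, 50)], gms)
        (s,) = gene_dark_stats(records, gms)
        assert s.pct_dark_CDS is None
        assert s.pct_dark_intron is None


class TestAuc:
    def _stats(self, pcts):
        return [
            type("S", (), {"gene_id": f"G{i}", "pct_dark_body": p})()
            for i, p in enumerate(pcts)
        ]

    def test_identity_ratio_is_one(self):
        a = self._stats([10.0, 20.0, 5.0])
        assert auc_comparison(a, a) == pytest.approx(1.0)

    def test_zero_dark_other_gives_zero(self):
        a = self._stats([10.0, 20.0, 5.0])
        b = self._stats([0.0, 0.0, 0.0])
        assert auc_comparison(a, b) == 0.0

    def test_halved_percentages_give_half(self):
        a = self._stats([10.0, 20.0, 5.0])
        b = self._stats([5.0, 10.0, 2.5])
        assert auc_comparison(a, b) == pytest.approx(0.5)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            auc_comparison([], [])


class TestDiseaseEnrichment:
    def _table(self, rng, n_genes=120, n_dis=12, p=0.15):
        rows = []
        for g in range(n_genes):
            for d in range(n_dis):
                if rng.random() < p:
                    rows.append((f"G{g}", f"D{d}"))
        return pd.DataFrame(rows, columns=["gene", "disease"])

    def test_score_formula_closed_forms(self):
        # p = 1 -> 0; p = 0.01 -> 20; p = 1/10001 -> 40
        assert round(-10 * np.log10(1.0)) == 0
        assert round(-10 * np.log10(0.01)) == 20
        assert round(-10 * np.log10(1 / 10001)) == 40

    def test_observed_never_exceeded_gives_score_forty(self, rng):
        # a disease annotated to exactly the dark genes and nothing else
        table = self._table(rng)
        dark = [f"G{i}" for i in range(15)]
        table = pd.concat(
            [table, pd.DataFrame({"gene": dark, "disease": "DX"})],
            ignore_index=True,
        )
        res = disease_enrichment(dark, table, n_perm=10_000, seed=1)
        row = res[res["disease"] == "DX"].iloc[0]
        # every dark gene is annotated to DX; permutations essentially
        # never reach the observed count, so p = 1/10001 and score 40
        assert row["observed"] == len(dark)
        assert row["p_value"] == pytest.approx(1 / 10001)
        assert row["score"] == 40

    def test_reproducible_for_fixed_seed(self, rng):
        table = self._table(rng)
        dark = [f"G{i}" for i in range(10)]
        a = disease_enrichment(dark, table, n_perm=500, seed=42)
        b = disease_enrichment(dark, table, n_perm=500, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_null_pvalues_roughly_uniform(self, rng):
        # two diseases so the gene universe is wider than either disease's
        # annotation set; D0 covers about half the genes
        table = self._table(rng, n_genes=200, n_dis=2, p=0.5)
        pvals = []
        gene_pool = table["gene"].unique()
        for _ in range(150):
            dark = rng.choice(gene_pool, size=40, replace=False).tolist()
            res = disease_enrichment(dark, table, n_perm=400, rng=rng)
            pvals.append(res.set_index("disease").loc["D0", "p_value"])
        pvals = np.asarray(pvals)
        # permutation p-values are discrete; check location and spread
        assert 0.35 < pvals.mean() < 0.7
        d = sps.kstest(pvals, "uniform").statistic
        assert d < 0.25

    def test_invalid_inputs_rejected(self, rng):
        table = self._table(rng)
        with pytest.raises(ValueError):
            disease_enrichment(["G0"], table, n_perm=0)
        with pytest.raises(ValueError):
            disease_enrichment(["G0"], pd.DataFrame(columns=["gene", "disease"]))
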