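# camodark

Detection of dark and camouflaged genomic regions in short-read
sequencing data, and rescue of variants hidden inside camouflaged
regions — as a Python library with a thin command-line interface.

## The problem

Standard short-read sequencing leaves parts of the genome effectively
invisible to variant callers:

- **Dark by depth** — too few reads align (≤ 5 aligned reads at a
  position): there is simply no data.
- **Dark by mapping quality** — reads align, but ≥ 90% of them carry
  MAPQ < 10, so callers discard them.  Most such regions are
  **camouflaged**: a near-identical duplication elsewhere (or within the
  same gene) makes read placement ambiguous, and aligners such as BWA
  place each multi-mapping read at one of the candidate loci uniformly
  at random with MAPQ 0.

Clinically important genes sit in such regions — genes camouflaged by a
paralog (the *SMN1*/*SMN2* or *HSPA1A*/*HSPA1B* pattern) or by repeats
of themselves (the *CR1*/*NEB* pattern, where several CDS exons are
identical in the reference).  Mutations there go uncalled in every
standard pipeline, whole-genome or exome.

## The method

1. **Scan** — classify every position from per-position depth and
   low-MAPQ counts averaged across samples (depth ≤ 5 → dark by depth,
   else low-MAPQ mass ≥ 90% → dark by MAPQ); assemble maximal runs of
   ≥ 20 contiguous bases into dark regions and intersect them with
   flattened gene models, splitting at every element boundary
   (CDS/UTR/ncRNA exon/intron).
2. **Camo discovery** — find the ≥ 98%-identical partners of each
   dark-by-MAPQ region (exact k-mer seeding + affine-gap local
   alignment; identity counted over alignment columns, gaps included)
   and group regions into *camo sets* by transitive closure.  A set of
   *c* copies is treated as one pooled locus of ploidy 2*c*.
3. **Mask & realign** — mask every copy except one representative to
   `N` in the reference and realign the extracted MAPQ < 10 reads of
   the whole set to the representative; with no competing locus the
   placement is unique.
4. **Call at set ploidy** — per column, choose the alt copy number
   k ∈ {0..P} maximizing the pooled-haplotype likelihood, where each
   read shows the alt allele with probability
   `(k/P)(1−ε) + (1−k/P)ε`.  A heterozygous variant in one copy of a
   3-copy set is expected in ~1/6 of reads — far below the diploid
   expectation of 1/2, which is why ploidy must be raised.
5. **Filter** — drop calls at *reference-based artifact* positions
   (sites where the set's copies differ in the reference itself,
   derived by locally aligning each copy back to the representative
   with match 1 / mismatch −3 / gap open −5 / gap extend −2), and calls
   with quality-by-depth QD ≤ 2 (stringent: ≤ 3).

A first-class synthetic-data module simulates the entire setting —
diploid genome, duplication families with tunable identity, random
placement of multi-mapping reads at MAPQ 0, planted variants, truth
sets — so every stage is verifiable without restricted datasets.

## Worked example

`python examples/05_rescue_pipeline.py` simulates a gene whose three
300-nt CDS exons are ~99.3% identical copies, with a heterozygous 10-nt
frameshift deletion planted in the second copy, and runs the full
pipeline:

```
planted: heterozygous 10-nt deletion in copy 2 of 3 at chr1:1250 (expected pooled alt fraction 0.167)

discovered set_1: 3 exons, ploidy 6, intra-gene: True
artifact positions from reference divergence: 4

calls on the representative exon:
  chr1:550  TTGTAAGGCAC>T  alt copies 1/6  depth 119  QD 6.12  PASS
```

The deletion is recovered on the representative exon as a PASS call
with allele count 1 of 6 (one haplotype of one copy; genotype
`0/0/0/0/0/1` in the emitted VCF).  The four reference-divergence sites
between the exon copies are screened as artifacts, and pooled short
reads cannot tell *which* of the three exons carries the mutation —
that requires targeted follow-up.

The other examples cover scanning (`01`), gene annotation statistics
(`02`), camo sets and masking (`03`), artifact screening (`04`) and the
disease-enrichment permutation test (`06`).  The same stages are
available as shell subcommands:

```bash
camodark simulate --spec spec.json --out-prefix sim
camodark scan --sam sim.sam --ref sim.fasta --out-dark dark.bed
camodark camo --dark dark.bed --ref sim.fasta --gtf sim.gtf \
    --out-sets sets.bed --out-masked-ref masked.fasta --out-maskplan plan.json
camodark screen-artifacts --sets sets.bed --ref sim.fasta --out artifacts.bed
camodark rescue --sam sim.sam --camo-bed sets.bed --maskplan plan.json \
    --masked-ref masked.fasta --artifacts artifacts.bed --out rescued.vcf
```

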