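# Methods

This note documents the models, parameter choices and numerical
decisions behind `camodark`, and what the synthetic-data studies do and
do not establish about real sequencing data.

## Dark-region classification

Positions are classified from multi-sample-averaged evidence.  For each
sample, depth at a position counts reads with an *aligned base* there:
CIGAR deletions/skips spanning a position contribute nothing, nor do
soft-clipped bases.  Duplicate-flagged, secondary and supplementary
records are excluded by default (configurable); this matches common
depth-calling practice, though whether duplicate reads should count
toward the depth threshold is genuinely underdetermined — the default
is the conservative choice.

Depth and low-MAPQ counts are averaged across samples first, and the
thresholds applied to the averages (mean-then-threshold, with the
low-MAPQ fraction recomputed from the averaged numerator and
denominator).  Thresholds, all inclusive as written:

| parameter | default | meaning |
|---|---|---|
| `dark_depth_max` | 5 | dark by depth when depth ≤ 5 |
| `mapq_low_max` | 9 | a read is "low MAPQ" when MAPQ < 10 |
| `dark_mass_min_pct` | 90.0 | dark by MAPQ when ≥ 90% of aligned reads are low-MAPQ |
| `camo_mass_min_pct` | 50.0 | partner admission threshold during camo discovery |
| `min_region_size` | 20 | regions of < 20 contiguous bases are dropped in analysis |

The two classes are mutually exclusive with depth checked first: a
position with ≤ 5 reads is dark by depth even if all its reads are
low-MAPQ.  Raising `dark_depth_max` can only grow the dark-by-depth
set; raising `dark_mass_min_pct` can only shrink the dark-by-MAPQ set
(verified as property tests).

## Gene flattening and element statistics

Transcripts are flattened per gene by labelling every base with the
highest-precedence label across transcripts: CDS > UTR5/UTR3 >
ncRNA exon > intron.  The precedence is a design choice (annotation
formats do not dictate one); it makes the element categories mutually
exclusive so per-category dark-base counts add up.  Exonic bases of
coding genes not covered by any CDS/UTR sub-feature cannot be assigned
a UTR side; they default to UTR5 and are tallied in
`GeneModel.n_unresolved_utr`.

Dark regions are clipped to gene spans and split at element boundaries;
piece lengths conserve the clipped overlap exactly (property-tested on
random region/gene pairs).  A region overlapping several genes
contributes to each gene's statistics (flagged `multi_gene`), so a
gene's percent-dark never depends on its neighbours.  Percentages are
100 × dark bases / category bases; a zero-length category yields
`None` rather than a number.

The AUC comparison between technologies is the ratio of the summed
per-gene percent-dark values, other technology over reference, so the
reference scores 1.0 by construction.  The disease-enrichment score for
a dark gene set of size *n* draws *n* genes from the table's gene
universe 10,000 times; the empirical p-value uses the +1 pseudo-count,
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)` (never exactly zero, ceiling
score 40 at 10,000 permutations), and the score is
`round(−10·log10 p)`.

## Similarity search and camo sets

Partners of a dark-by-MAPQ region are found with exact 11-mer seeding
clustered by diagonal, followed by affine-gap local alignment of each
candidate window.  Identity is counted over *alignment columns
including gap columns* (the convention of BLAT-style percent identity);
this is stated explicitly because it decides borderline 98% calls.
Hits must also cover ≥ 50% of the query, so incidental seed collisions
never qualify.  The trivial self-hit is removed by interval overlap.

Camo sets are the connected components (union-find) of the qualifying-
hit graph — transitive closure, so the set's ploidy counts every copy a
read could have come from even when two members fall just below 98%
identity with each other.  Set membership additionally requires the
partner to carry ≥ 50% low-MAPQ mass when per-position mass is
available.  The representative is the left-most region on the
lowest-ordered contig (deterministic); overlapping sets are merged
before masking, and it is a hard error for any mask to touch a
representative.  Masking writes `N` over every non-representative
region, preserving contig lengths.

Rescue operates on whole camouflaged CDS exons: a dark core inside an
exon marks the entire exon as the camouflaged unit
(`camo_candidate_regions`), since the exon is what gets masked and what
reads are pooled over.

## Pairwise alignment engine

One Gotoh affine-gap implementation (numpy-vectorised rows; the
within-row horizontal-gap recurrence solved as a running-max prefix
scan) serves two modes:

- **local** for region-vs-region comparison and artifact screening,
  with the scoring fixed at match 1, mismatch −3, gap open −5, gap
  extend −2; a gap of length L costs `open + (L−1)·extend`, i.e. the
  open penalty is charged on the first gap column.
- **fit (glocal)** for read realignment: the whole read must align
  against a substring of the representative window.  Local alignment
  would soft-clip a variant near a read end whenever the flank is worth
  less than the gap penalty; fit mode keeps the 10-nt deletion CIGAR in
  those reads.  Terminal query-only columns become soft clips; reads
  scoring below 50% of a perfect match are discarded as unrelated.

`N` never matches anything, so masked reference stretches cannot
attract alignments.  The engine is checked against an exhaustive
quadratic DP oracle and against Biopython's `PairwiseAligner` in tests.

## Ploidy-aware genotype model

For a camo set with repeat count *c*, pooled reads sample P = 2*c*
haplotypes.  With k alt copies, a read shows the alt allele with
probability `(k/P)(1−ε) + (1−k/P)ε` under symmetric error ε; column
genotypes maximize this likelihood over k ∈ {0..P} (exhaustively —
P is small), optionally weighted by a prior.  Defaults:

- `base_error_rate ε = 0.001` for substitutions (Q30, the operating
  point of modern short reads; the simulator plants errors at the same
  rate).  A coarser ε would understate per-read evidence enough that a
  true 1-of-6 allele at ~100× pooled depth could not clear the QD
  filter that defines the call set.
- `indel_error_rate = 1e-5`: the probability that a read displays a
  clean multi-base alignment gap by error is far below the substitution
  rate (a spurious 10-nt deletion must beat 23 penalty points of gap
  cost during realignment).
- `variant_prior = 1e-3`, split uniformly over k ≥ 1 — the standard
  heterozygosity-style prior.  Without it the maximum-likelihood k
  chases a single mismatching read at shallow pileup columns; with it
  such columns are called hom-ref.  Setting `variant_prior=None`
  recovers pure maximum likelihood (used when cross-checking against
  the enumeration oracle).

`qual` is the phred-scaled posterior mass on k = 0; QD = qual / number
of reads informative at the site.  This reproduces the *semantics* of
the quality-by-depth filter (QD ≤ 2 removed, ≤ 3 stringent) without
claiming to reproduce any external caller's numeric QUAL.  Indel events
are left-normalized before aggregation, so equivalent gap placements
reported by different reads merge into one variant, and emitted indels
follow the VCF left-anchor convention (deletion: REF = anchor + deleted
bases, ALT = anchor).

Ti/Tv of PASS SNVs is reported with transitions {A↔G, C↔T}; a call set
with no transversions reports `titv = None` rather than a division by
zero.

## Artifact screening

Each non-representative copy of a set is locally aligned back to the
representative with the fixed scoring above; every mismatch column
becomes a substitution artifact at `representative_start +
query_offset`, and every gap *run* becomes a single record anchored at
the column preceding the gap (VCF-style left anchor; one record per
gap, not per gap column — the per-column alternative would only
multiply records at the same filterable locus).  Copies aligning below
98% identity are not qualifying hits; sets repeated more than 5 times
are excluded from screening but still rescued, and are reported as
skipped.  During filtering, a variant is an artifact if *any* reference
base it spans is an artifact position.

## The simulator and what it shows

The generator's defaults are the study conditions: 100-nt single-end
reads at 37.5× mean depth (the rescue studies use 40× per copy),
substitution errors at 0.001, diploid individuals (two haplotypes per
copy; planted variants sit on one haplotype unless marked homozygous).
Duplication families are written into random background with ≥ 3
read-length unique flanks; divergent sites are substitutions placed
≥ 10 nt from segment edges with ≥ 5 nt separation so each is a clean
alignment column, and `divergence_zone` can confine them near one edge,
leaving a long identical core — the configuration that produces a
contiguous dark-by-MAPQ region under 100-nt reads.

Multi-mapping is decided by *reference-footprint identity*: a read
placed at p is ambiguous iff the reference under its alignment
footprint at p is byte-identical at the homologous offset of another
copy; ambiguous reads are placed uniformly at random among the
equal-best loci with MAPQ 0, unique reads get MAPQ 60.  For reads
without planted variants this is exactly exact-substring-equality of
the error-free read against each copy; for variant-carrying reads it
reproduces what a score-based aligner does (the read is equally
mismatched against every identical copy).  Errors are applied after
placement, so placement is deterministic given the genome.

The truth set includes the conservative dark-by-MAPQ expectation:
positions whose *every* covering read-length window is ambiguous.  The
scanner recovers ≥ 95% of those bases and calls < 1% of unique-flank
bases dark (averaged over 10 seeds); the residual false darkness is the
depth ramp at contig ends, which real whole-genome data does not have
at this relative magnitude.

What the simulator deliberately omits: paired-end inserts (single-end
suffices to exercise every classifier and caller path; BWA's mate-
rescue behaviour, which can give multi-mapping reads high MAPQ, is
therefore not modelled), base-quality variation and GC bias, indel
sequencing errors, and divergence by indels between copies (the
artifact screen handles gap artifacts, exercised with hand-constructed
copies in tests).  Passing the synthetic studies therefore demonstrates
the algorithmic contracts — classification thresholds, set
construction, masking, pooled-ploidy genotype semantics, artifact
completeness — not calibration against any particular instrument or
aligner.

## Problem sizes

The end-to-end rescue studies run on 9 kb genomes with a 3-copy 300-nt
intra-gene family at 40× per copy (≈ 3,600 reads per replicate), 100
replicates with and 100 without the planted deletion in the test suite
(40 + 40 in the acceptance script); the dark-scan recall study uses
8 kb genomes over 10 seeds; alignment oracles use 500 random pairs up
to 30 nt; classifier oracles use 10,000 random pileups.  These sizes
were chosen so each study isolates one mechanism while the whole suite
stays desk-scale and deterministic.

## Known limitations

- Rescue assigns a variant to the camo *set*, never to a specific copy;
  that requires targeted follow-up sequencing by design.
- QD semantics are reproduced, not any external caller's exact QUAL;
  absolute qual values are not comparable across callers.
- The similarity search is desk-scale (in-memory k-mer index of the
  whole genome); genome-wide all-vs-all discovery at human scale is out
  of scope, though an external search tool can be adapted in at the
  `SimilarityHit` boundary.
- Whether a region overlapping two genes should count once or twice in
  region-count tables is ambiguous; the per-gene convention here counts
  it for each gene and flags it, so downstream consumers can choose.
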