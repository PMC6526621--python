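"""Group camouflaged regions into sets and plan the reference masking.

Regions >= 98% identical (over alignment columns, transitively linked)
form one camo set; every set keeps a single unmasked representative.
The set's calling ploidy is 2 x repeat count — hexaploid for three
copies — because pooled reads sample that many haplotypes.
"""

import camodark as cd

spec = cd.SimSpec(
    genome_length=30_000,
    families=(
        cd.DuplicationFamily(copy_count=2, segment_length=300, identity_pct=100.0),
        cd.DuplicationFamily(copy_count=3, segment_length=300, identity_pct=99.0),
        cd.DuplicationFamily(copy_count=2, segment_length=300, identity_pct=97.0),
    ),
    seed=3,
)
genome, _, truth = cd.simulate_genome(spec)

regions = [
    cd.DarkRegion("chr1", s, e, "dark_by_mapq", 35.0, 98.0)
    for fam in truth.families
    for s, e in fam.copies
]
index = cd.KmerIndex(genome)
hits = {
    i: cd.find_similar_regions((r.contig, r.start, r.end), genome, 98.0, index=index)
    for i, r in enumerate(regions)
}
sets = cd.build_camo_sets(regions, hits)

print("camo sets (97%-identity decoy family forms none):")
for s in sets:
    ivs = ", ".join(f"{a}-{b}" for _, a, b in s.regions)
    print(f"  {s.set_id}: {s.repeat_count} copies (ploidy {s.ploidy}) at {ivs}")
print(f"repeat-count histogram: {cd.repeat_count_histogram(sets)}")

plan, masked, bed_rows = cd.plan_masking(sets, genome)
n_masked = sum(e - s for _, (rep, ms) in plan.plans.items() for _, s, e in ms)
print(f"\nmasked {n_masked} reference bases; representatives untouched:")
for set_id, (rep, ms) in plan.plans.items():
    print(f"  {set_id}: representative {rep[1]}-{rep[2]}, {len(ms)} copies masked to N")
print("after masking, a new similarity search from each representative finds nothing:")
print("  residual hits:", cd.find_similar_regions(sets[0].representative, masked))
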