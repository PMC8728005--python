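"""Detect telomeres/centromeres and split a mis-joined scaffold.

Generates chromosomes with terminal CCCT[A/C]AA telomere arrays and
clustered copies of the 148-bp centromeric unit, plus one 'fused'
scaffold joining two chromosomes. The curation stage must find the
repeats, merge centromere copies into regions, and split the fused
scaffold at its internal, outward-facing telomere arrays so no scaffold
keeps more than one centromeric region.
"""

from redwoodkit import scaffold_curation as sc
from redwoodkit import synthetic_data as sd

records, truth = sd.gen_scaffolds(sd.ScaffoldConfig(n_chromosomes=2, n_fused=1), seed=7)

telomeres = [h for r in records for h in sc.scan_telomeres(r)]
centromeres = [h for r in records for h in sc.scan_centromeres(r)]
# toy-scale arms (~20 kb): the merge radius scales with them
regions = sc.merge_centromeric_hits(centromeres, merge_distance=10_000)
curated, events = sc.split_scaffolds(records, regions, telomeres)
stats = sc.assembly_stats(curated, fixed_genome_size=300_000)

print(f"telomere arrays found   : {len(telomeres)}")
print(f"centromere hits/regions : {len(centromeres)} hits -> {len(regions)} regions")
for e in events:
    print(f"split {e.scaffold} at {e.position:,} (reason: {e.reason})")
print(f"scaffolds in/out        : {len(records)} -> {len(curated)}")
print(f"scaffold N50 / NG50     : {stats.scaffold_n50:,} / {stats.scaffold_ng50:,} bp")
labels = sc.classify_arms(curated, sc.merge_centromeric_hits(
    [h for r in curated for h in sc.scan_centromeres(r)], 10_000),
    [h for r in curated for h in sc.scan_telomeres(r)])
arms = sum(1 for v in labels.values() if v == "arm_with_telomere_end")
print(f"chromosome arms         : {arms} of {len(labels)} centromeric scaffolds end in a telomere")
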