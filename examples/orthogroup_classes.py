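"""Classify orthogroup copy-number patterns for a hexaploid focal species.

The matrix planter lays out species-specific families, families absent
from the Cupressaceae relatives, 2-fold expansions, and the 3:1:1 / 2:1:1
classes (three or two focal copies against single-copy diploid
relatives) that feed the polyploid-origin gene-tree analysis.
"""

from redwoodkit import orthogroup_analysis as oa
from redwoodkit import synthetic_data as sd

cfg = sd.OrthogroupConfig()
matrix, truth = sd.gen_orthogroups(cfg, seed=5)
report = oa.classify_all(matrix, cfg.focal, cfg.reference_species, cfg.clade_species)

for cls in ("species_specific", "absent_in_clade", "expanded", "contracted",
            "three_to_one", "two_to_one", "tandem_flagged"):
    fams = getattr(report, cls)
    planted = truth.get("tandem" if cls == "tandem_flagged" else cls, set())
    print(f"{cls:18s}: {len(fams):3d} families (planted truth: {len(planted)})")

candidates = oa.phylo_candidates(matrix, cfg.focal, cfg.reference_species, sample_n=10, seed=1)
print(f"\ngene-tree candidates (multicopy, >300 aa, within 75% of max length,")
print(f"tandem-excluded), deterministic sample of 10: {candidates}")
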