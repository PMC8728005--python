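"""Windowed nucleotide diversity and Weir-Cockerham Fst.

Simulates biallelic genotypes for two populations of 30 diploids under
the Balding-Nichols model at F = 0.05, then estimates windowed pi
(window 10,000 bp, step 1,000 bp) and the Weir-Cockerham fixation index
as the ratio of summed variance components. The estimate should recover
the simulated F.
"""

from redwoodkit import popgen as pg
from redwoodkit import synthetic_data as sd

cfg = sd.VariantConfig(n_loci=20_000, fst=0.05)
table = sd.gen_variants(cfg, seed=11)

pi_windows = pg.windowed_pi(table)
pi = pg.pi_summary(pi_windows, table)
comp, fst_windows = pg.wc_fst(table)
fst = pg.fst_summary(comp, fst_windows)

print(f"sites x samples        : {table.n_sites:,} x {table.n_samples}")
print(f"pi windows             : {len(pi_windows):,} (10 kb window, 1 kb step)")
print(f"mean pi over windows   : {pi['mean_pi_over_windows']:.6f} per bp")
print(f"mean pi over sites     : {pi['mean_pi_over_sites']:.6f}")
print(f"Fst (ratio of sums)    : {fst['global_ratio_of_sums']:.4f}")
print(f"Fst (mean over windows): {fst['mean_theta_over_windows']:.4f}")
print(f"simulated F            : {cfg.fst}")
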