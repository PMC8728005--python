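"""Kimura two-parameter distance and counting dN/dS between gene copies.

Simulates a coding sequence and a diverged copy, then estimates the K2P
nucleotide distance (separate transition/transversion rates) and the
NG86 counting dN/dS with Jukes-Cantor correction. Purifying selection
(here: amino-acid-preserving divergence) should give omega << 1, while
substitutions blind to codon structure give omega near 1.
"""

import numpy as np

from redwoodkit import molecular_evolution as me
from redwoodkit import synthetic_data as sd

rng = np.random.default_rng(2)
ancestor = sd._random_cds(rng, 2_000)

# purifying selection: only synonymous codon swaps survive (protein intact)
codons = [ancestor[i:i + 3] for i in range(0, len(ancestor), 3)]
for i in rng.choice(len(codons), round(0.15 * len(codons)), replace=False):
    aa = next(a for a, cs in sd._AA_CODON.items() if codons[i] in cs)
    codons[i] = str(rng.choice(sd._AA_CODON[aa]))
constrained = "".join(codons)

# neutral divergence: substitutions placed uniformly, ignoring codons
neutral = list(ancestor)
for i in rng.choice(len(neutral), round(0.08 * len(neutral)), replace=False):
    neutral[i] = "ACGT"[rng.integers(0, 4)]
neutral = "".join(neutral)

for name, seq in (("constrained", constrained), ("neutral", neutral)):
    k2p = me.kimura2p(ancestor, seq)
    dnds = me.pairwise_dnds(ancestor, seq)
    omega = f"{dnds.omega:.3f}" if dnds.omega is not None else "NA"
    print(f"{name:12s}: K2P={k2p.K:.4f} (P={k2p.P:.4f}, Q={k2p.Q:.4f})  "
          f"dN={dnds.dN:.4f} dS={dnds.dS:.4f} omega={omega}")
print("\nomega near 1 = neutral evolution; omega >> or << 1 = selection")
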