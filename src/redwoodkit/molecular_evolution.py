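"""Sequence-divergence estimators and the polyploid-origin topology test.

Divergence between gene copies is summarized by the Kimura two-parameter
distance (separate transition/transversion rates) on aligned nucleotides,
and by counting-based (Nei-Gojobori 1986) synonymous and nonsynonymous
substitution rates with Jukes-Cantor correction. dN/dS here is a
counting estimator, not a maximum-likelihood codon model; at the low
divergences it is applied to, the two agree closely, and the report marks
the method.

The origin test: if a polyploid arose by within-lineage genome doubling
(autopolyploidy), the multiple gene copies of the focal species should be
closer to each other than to any other species — they form a clade in
each gene tree. Copies branching inside another lineage instead indicate
a hybrid (allopolyploid) contribution from that donor. The classifier
roots each gene tree on a designated outgroup, tests focal-copy monophyly,
and, when monophyletic, identifies the sister lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import dendropy

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
VALID_BASES = set("ACGT")

_CODON_AA: dict[str, str] = {}


def _build_code() -> None:
    from Bio.Seq import Seq

    bases = "TCAG"
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                codon = b1 + b2 + b3
                _CODON_AA[codon] = str(Seq(codon).translate())


_build_code()


# ---------------------------------------------------------------------------
# Kimura 2-parameter


@dataclass
class PairwiseDistance:
    P: float  # transition proportion
    Q: float  # transversion proportion
    K: float | None  # K2P distance; None when saturated
    sites_used: int

    @property
    def saturated(self) -> bool:
        return self.K is None


def kimura2p(seq_a: str, seq_b: str) -> PairwiseDistance:
    """K2P distance on an aligned pair, with pairwise deletion.

    Columns holding a gap or ambiguity code in either sequence are
    excluded. K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)); when the log
    arguments are nonpositive the distance is undefined (saturation).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    transitions = transversions = used = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in VALID_BASES or b not in VALID_BASES:
            continue
        used += 1
        if a == b:
            continue
        if (a, b) in TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if used == 0:
        raise ValueError("no comparable sites")
    p, q = transitions / used, transversions / used
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    k = None
    if w1 > 0 and w2 > 0:
        k = -0.5 * math.log(w1 * math.sqrt(w2))
    return PairwiseDistance(P=p, Q=q, K=k, sites_used=used)


# ---------------------------------------------------------------------------
# Nei-Gojobori counting dN/dS


@dataclass
class CodonSubstResult:
    N: float  # nonsynonymous sites (average of both sequences)
    S: float  # synonymous sites
    Nd: float  # nonsynonymous differences
    Sd: float  # synonymous differences
    pN: float
    pS: float
    dN: float | None  # None = saturated
    dS: float | None
    omega: float | None  # None when dS is 0 or undefined
    codons_used: int
    method: str = "NG86+JC"


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon; nonsense changes disregarded."""
    s = 0.0
    aa = _CODON_AA[codon]
    for pos in range(3):
        syn = tot = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt_aa = _CODON_AA[codon[:pos] + nt + codon[pos + 1 :]]
            if alt_aa == "*":
                continue
            tot += 1
            if alt_aa == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s


def _path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal
    mutational pathways; pathways crossing a stop codon are excluded
    (uniform weights over the survivors)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0
        crosses_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_AA[nxt] == "*":
                crosses_stop = True
            if _CODON_AA[nxt] == _CODON_AA[cur] and _CODON_AA[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if crosses_stop else results).append((sd, nd))
    pool = results or fallback
    return (
        sum(r[0] for r in pool) / len(pool),
        sum(r[1] for r in pool) / len(pool),
    )


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def pairwise_dnds(cds_a: str, cds_b: str) -> CodonSubstResult:
    """NG86 counting dN/dS on an aligned coding pair.

    Codons holding a gap/ambiguity or a stop in either sequence are
    excluded pairwise. Sites are averaged over both sequences; observed
    differences follow minimal mutational pathways with uniform weights.
    Jukes-Cantor correction maps proportions to rates; omega is reported
    as None when dS is 0 or either rate is saturated.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("coding sequences must be aligned to equal length")
    if len(cds_a) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    a, b = cds_a.upper(), cds_b.upper()
    s_a = s_b = sd = nd = 0.0
    used = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (set(ca) <= VALID_BASES and set(cb) <= VALID_BASES):
            continue
        if _CODON_AA[ca] == "*" or _CODON_AA[cb] == "*":
            continue
        used += 1
        s_a += _syn_sites(ca)
        s_b += _syn_sites(cb)
        if ca != cb:
            d_s, d_n = _path_differences(ca, cb)
            sd += d_s
            nd += d_n
    if used == 0:
        raise ValueError("no comparable codons")
    s_sites = (s_a + s_b) / 2
    n_sites = 3 * used - s_sites
    p_s = sd / s_sites if s_sites else 0.0
    p_n = nd / n_sites if n_sites else 0.0
    d_s = _jukes_cantor(p_s)
    d_n = _jukes_cantor(p_n)
    omega = None
    if d_n is not None and d_s is not None and d_s > 0:
        omega = d_n / d_s
    return CodonSubstResult(
        N=n_sites,
        S=s_sites,
        Nd=nd,
        Sd=sd,
        pN=p_n,
        pS=p_s,
        dN=d_n,
        dS=d_s,
        omega=omega,
        codons_used=used,
    )


# ---------------------------------------------------------------------------
# Gene-tree topology classification


@dataclass
class TopologyCall:
    tree_id: str
    focal_monophyletic: bool
    n_focal_copies: int
    sister: str  # candidate name or "unclear"; "" when non-monophyletic
    support_at_focal_clade: float | None = None


def species_of_leaf(label: str) -> str:
    """Default leaf-name convention: ``SPECIES_copyindex``."""
    return label.rsplit("_", 1)[0]


def classify_topology(
    tree: dendropy.Tree,
    focal_species: str,
    candidate_sisters: tuple[str, ...] = ("GS", "MG"),
    outgroup: str = "OUT",
    support_threshold: float | None = None,
    tree_id: str = "",
    species_of=species_of_leaf,
) -> TopologyCall:
    """Root on the outgroup, test focal-copy monophyly, assign the sister.

    The sister is the candidate species found (alone, or as the only
    candidate) in the sibling subtree of the focal clade; when both or
    neither candidate appears there — or the clade support falls below
    ``support_threshold`` when one is set — the call is "unclear".
    Midpoint rooting is deliberately not offered: an explicit outgroup is
    required for the monophyly statement to be meaningful.
    """
    work = tree.clone(depth=1)
    leaves = list(work.leaf_node_iter())
    out_leaves = [l for l in leaves if species_of(l.taxon.label) == outgroup]
    if not out_leaves:
        raise ValueError(f"outgroup {outgroup!r} not present in tree")
    focal_leaves = [l for l in leaves if species_of(l.taxon.label) == focal_species]
    if len(focal_leaves) < 2:
        raise ValueError("need at least two focal copies to classify")

    if len(out_leaves) == 1:
        work.reroot_at_edge(out_leaves[0].edge, update_bipartitions=False)
    else:
        mrca = work.mrca(taxa=[l.taxon for l in out_leaves])
        if mrca is not work.seed_node:
            work.reroot_at_edge(mrca.edge, update_bipartitions=False)

    focal_taxa = [l.taxon for l in focal_leaves]
    mrca = work.mrca(taxa=focal_taxa)
    clade_leaves = list(mrca.leaf_iter())
    mono = len(clade_leaves) == len(focal_leaves)

    support: float | None = None
    if mono and mrca.label is not None:
        try:
            support = float(mrca.label)
        except ValueError:
            support = None

    sister = ""
    if mono:
        parent = mrca.parent_node
        sibling_species: set[str] = set()
        if parent is not None:
            for child in parent.child_nodes():
                if child is mrca:
                    continue
                sibling_species.update(
                    species_of(l.taxon.label) for l in child.leaf_iter()
                )
        present = [c for c in candidate_sisters if c in sibling_species]
        sister = present[0] if len(present) == 1 else "unclear"
        if (
            support_threshold is not None
            and support is not None
            and support < support_threshold
        ):
            sister = "unclear"
    return TopologyCall(
        tree_id=tree_id,
        focal_monophyletic=mono,
        n_focal_copies=len(focal_leaves),
        sister=sister,
        support_at_focal_clade=support,
    )


def tally_topologies(
    calls: list[TopologyCall], candidate_sisters: tuple[str, ...] = ("GS", "MG")
) -> dict[str, object]:
    """Count topology classes, with a 2-copy vs 3-copy breakdown."""

    def _zero() -> dict[str, int]:
        d = {f"monophyletic_sister_{c}": 0 for c in candidate_sisters}
        d["monophyletic_unclear"] = 0
        d["non_monophyletic"] = 0
        return d

    total = _zero()
    by_copy: dict[int, dict[str, int]] = {}
    for call in calls:
        if call.focal_monophyletic:
            key = (
                f"monophyletic_sister_{call.sister}"
                if call.sister in candidate_sisters
                else "monophyletic_unclear"
            )
        else:
            key = "non_monophyletic"
        total[key] += 1
        by_copy.setdefault(call.n_focal_copies, _zero())[key] += 1
    result: dict[str, object] = dict(total)
    result["n_trees"] = len(calls)
    result["by_copy_number"] = by_copy
    return result
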