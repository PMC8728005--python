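"""Orthogroup copy-number classification for a hexaploid focal species.

Given a family x species copy-count matrix (plus per-gene protein lengths
and genomic positions), this module extracts the comparative-genomics
classes that bear on ploidy and adaptation: species-specific families,
families absent from a clade, >= 2-fold expansions/contractions, the
3:1:1 and 2:1:1 copy classes against diploid relatives, tandem-duplicate
flags, candidate families for gene-tree analysis, and genes lying near
Copia retrotransposon insertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio import Align

from .core import IntervalRecord, OrthogroupMatrix

DEFAULT_FOLD = 2.0
DEFAULT_TANDEM_SEPARATION = 100_000
DEFAULT_MIN_LEN_AA = 300
DEFAULT_MIN_FRAC_OF_MAX = 0.75
DEFAULT_COPIA_WINDOW = 3_000


@dataclass
class CopyClassReport:
    species_specific: list[str] = field(default_factory=list)
    absent_in_clade: list[str] = field(default_factory=list)
    expanded: list[str] = field(default_factory=list)
    contracted: list[str] = field(default_factory=list)
    three_to_one: list[str] = field(default_factory=list)
    two_to_one: list[str] = field(default_factory=list)
    tandem_flagged: list[str] = field(default_factory=list)
    parameters: dict[str, object] = field(default_factory=dict)


def species_specific(matrix: OrthogroupMatrix, focal: str) -> list[str]:
    """Families present in the focal species and absent in every other."""
    c = matrix.counts
    if c.empty or focal not in c.columns:
        return []
    others = [s for s in c.columns if s != focal]
    mask = (c[focal] > 0) & (c[others].sum(axis=1) == 0)
    return list(c.index[mask])


def absent_in_set(
    matrix: OrthogroupMatrix, focal: str, excluded_species: Iterable[str]
) -> list[str]:
    """Families present in focal but absent from every excluded species;
    species outside the excluded set are unconstrained."""
    c = matrix.counts
    if c.empty or focal not in c.columns:
        return []
    excluded = [s for s in excluded_species if s != focal]
    mask = c[focal] > 0
    for s in excluded:
        mask &= c[s] == 0
    return list(c.index[mask])


def fold_deviation(
    matrix: OrthogroupMatrix, focal: str, fold: float = DEFAULT_FOLD
) -> tuple[list[str], list[str]]:
    """Families whose focal count deviates >= ``fold`` from the baseline.

    The baseline is the mean count over non-focal species that possess the
    family (count > 0). Focal-only families have no baseline and are
    skipped. Expanded: focal >= fold x baseline; contracted: focal <=
    baseline / fold.
    """
    c = matrix.counts
    if c.empty or focal not in c.columns:
        return [], []
    others = [s for s in c.columns if s != focal]
    expanded: list[str] = []
    contracted: list[str] = []
    for fam in c.index:
        row = c.loc[fam, others]
        present = row[row > 0]
        if c.loc[fam, focal] == 0 or present.empty:
            continue
        baseline = float(present.mean())
        n_focal = int(c.loc[fam, focal])
        if n_focal >= fold * baseline:
            expanded.append(fam)
        elif n_focal <= baseline / fold:
            contracted.append(fam)
    return expanded, contracted


def copy_class(
    matrix: OrthogroupMatrix,
    focal: str,
    reference_species: Iterable[str],
    focal_copies: int,
    ref_copies: int = 1,
) -> list[str]:
    """Families with exactly ``focal_copies`` in the focal species and
    ``ref_copies`` in every reference species (e.g., the 3:1:1 class)."""
    c = matrix.counts
    if c.empty or focal not in c.columns:
        return []
    mask = c[focal] == focal_copies
    for s in reference_species:
        mask &= c[s] == ref_copies
    return list(c.index[mask])


def flag_tandem(
    matrix: OrthogroupMatrix,
    focal: str,
    max_separation_bp: int = DEFAULT_TANDEM_SEPARATION,
) -> dict[str, bool]:
    """Flag families with >= 2 focal members on one scaffold within
    ``max_separation_bp`` of each other (likely tandem duplicates)."""
    meta = matrix.gene_meta
    focal_meta = meta[meta["species"] == focal]
    flags = {fam: False for fam in matrix.families}
    for fam, grp in focal_meta.groupby("family"):
        if fam not in flags:
            continue
        for _, sub in grp.groupby("scaffold"):
            starts = np.sort(sub["start"].to_numpy())
            if len(starts) >= 2 and np.any(np.diff(starts) <= max_separation_bp):
                flags[fam] = True
                break
    return flags


def phylo_candidates(
    matrix: OrthogroupMatrix,
    focal: str,
    reference_species: Iterable[str],
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    min_frac_of_max: float = DEFAULT_MIN_FRAC_OF_MAX,
    max_separation_bp: int = DEFAULT_TANDEM_SEPARATION,
    sample_n: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Select multicopy families suitable for gene-tree analysis.

    A family qualifies when the focal copy number is 2 or 3, every
    reference species has exactly 1 copy, every member protein is strictly
    longer than ``min_len_aa``, every member reaches at least
    ``min_frac_of_max`` of the family's maximum protein length, and the
    family is not tandem-flagged. With ``sample_n`` set, a deterministic
    random sample under ``seed`` is returned (all families, with a
    warning-free fallback, when fewer qualify).
    """
    refs = list(reference_species)
    multicopy = set(copy_class(matrix, focal, refs, 2)) | set(
        copy_class(matrix, focal, refs, 3)
    )
    tandem = flag_tandem(matrix, focal, max_separation_bp)
    meta = matrix.gene_meta
    passing: list[str] = []
    for fam in matrix.families:
        if fam not in multicopy or tandem.get(fam, False):
            continue
        lengths = meta.loc[meta["family"] == fam, "length_aa"].to_numpy()
        if len(lengths) == 0:
            continue
        if np.all(lengths > min_len_aa) and np.all(
            lengths >= min_frac_of_max * lengths.max()
        ):
            passing.append(fam)
    if sample_n is None or sample_n >= len(passing):
        return passing
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(passing, size=sample_n, replace=False).tolist())


def copia_proximity(
    gene_intervals: list[IntervalRecord],
    copia_intervals: list[IntervalRecord],
    window: int = DEFAULT_COPIA_WINDOW,
) -> list[str]:
    """Genes with a Copia insertion overlapping or within ``window`` bp of
    the gene span, same scaffold, strand-agnostic."""
    by_scaffold: dict[str, list[IntervalRecord]] = {}
    for iv in copia_intervals:
        by_scaffold.setdefault(iv.scaffold, []).append(iv)
    out: list[str] = []
    for g in gene_intervals:
        for c in by_scaffold.get(g.scaffold, []):
            if c.start < g.end + window and g.start < c.end + window:
                out.append(g.label)
                break
    return out


def ltr_span_ratio(spans_bp: Mapping[str, float], a: str = "Copia", b: str = "Gypsy") -> float:
    """Ratio of two LTR superfamily genomic spans (a : b)."""
    if spans_bp[b] <= 0:
        raise ValueError("denominator span must be positive")
    return spans_bp[a] / spans_bp[b]


def classify_all(
    matrix: OrthogroupMatrix,
    focal: str,
    reference_species: Iterable[str],
    clade_species: Iterable[str] | None = None,
    fold: float = DEFAULT_FOLD,
    max_separation_bp: int = DEFAULT_TANDEM_SEPARATION,
) -> CopyClassReport:
    """One-call summary of all copy-number classes."""
    refs = list(reference_species)
    clade = list(clade_species) if clade_species is not None else refs
    expanded, contracted = fold_deviation(matrix, focal, fold)
    tandem = flag_tandem(matrix, focal, max_separation_bp)
    return CopyClassReport(
        species_specific=species_specific(matrix, focal),
        absent_in_clade=absent_in_set(matrix, focal, clade),
        expanded=expanded,
        contracted=contracted,
        three_to_one=copy_class(matrix, focal, refs, 3),
        two_to_one=copy_class(matrix, focal, refs, 2),
        tandem_flagged=[f for f, v in tandem.items() if v],
        parameters={
            "focal": focal,
            "reference_species": refs,
            "clade_species": clade,
            "fold": fold,
            "max_separation_bp": max_separation_bp,
        },
    )


# ---------------------------------------------------------------------------
# Greedy identity clustering (duplication status)

_cluster_aligner = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-0.5,
)


def _pair_identity(a: str, b: str) -> float:
    """Identity = matching residues / length of the shorter sequence."""
    if not a or not b:
        return 0.0
    alns = _cluster_aligner.align(a, b)
    if len(alns) == 0:
        return 0.0
    return alns[0].counts().identities / min(len(a), len(b))


def greedy_cluster(proteins: dict[str, str], min_identity: float = 0.70) -> list[list[str]]:
    """Greedy centroid clustering of proteins at an identity threshold.

    Sequences are visited longest-first; each joins the first existing
    cluster whose centroid it matches at >= ``min_identity`` (identity
    measured over the shorter sequence), else founds a new cluster. This is
    a deliberately simple stand-in for heuristic centroid clusterers used
    to call duplication status.
    """
    order = sorted(proteins, key=lambda k: (-len(proteins[k]), k))
    centroids: list[str] = []
    clusters: list[list[str]] = []
    for name in order:
        seq = proteins[name]
        for i, cname in enumerate(centroids):
            if _pair_identity(seq, proteins[cname]) >= min_identity:
                clusters[i].append(name)
                break
        else:
            centroids.append(name)
            clusters.append([name])
    return clusters
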