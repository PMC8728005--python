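"""Shared in-memory containers used across the pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; GFF3/VCF
(1-based inclusive) are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, case preserved."""
    return seq.translate(COMPLEMENT)[::-1]


def softmask_fraction(seq: str) -> float:
    """Fraction of lowercase (repeat-masked) bases in a sequence span."""
    if not seq:
        return 0.0
    return sum(1 for b in seq if b.islower()) / len(seq)


@dataclass
class SequenceRecord:
    """A FASTA record; lowercase bases mark softmasked (repeat) sequence."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def softmask_fraction(self) -> float:
        return softmask_fraction(self.sequence)


@dataclass
class IntervalRecord:
    """BED-style genomic interval (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class KmerHistogram:
    """Histogram of k-mer multiplicities: distinct k-mer count per coverage.

    ``coverages`` are strictly increasing positive integers (the X axis of a
    Jellyfish ``histo`` output); ``counts`` are the numbers of distinct
    k-mers seen at each coverage.
    """

    k: int
    coverages: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.coverages = np.asarray(self.coverages, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.coverages.shape != self.counts.shape:
            raise ValueError("coverages and counts must have equal length")
        if len(self.coverages) and (
            np.any(np.diff(self.coverages) <= 0) or self.coverages[0] < 1
        ):
            raise ValueError("coverages must be strictly increasing positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def bins(self) -> list[tuple[int, int]]:
        return list(zip(self.coverages.tolist(), self.counts.tolist()))

    def total_instances(self) -> int:
        """Sum of coverage x count over all bins (total k-mer instances)."""
        return int(np.sum(self.coverages * self.counts))


@dataclass
class EvidenceFlags:
    """Functional-annotation outcomes attached to a gene model."""

    has_similarity_hit: bool = False
    domain_count: int = 0
    has_family_assignment: bool = False
    retro_domain_flag: bool = False


@dataclass
class GeneModel:
    """A predicted or transcriptome-derived gene model.

    ``exons`` and ``cds`` are lists of (start, end) 0-based half-open
    intervals in genomic order; ``cds_seq`` is the spliced,
    strand-corrected coding sequence when available.
    """

    id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    protein: str = ""
    cds_seq: str = ""
    softmask_fraction: float = 0.0
    evidence: EvidenceFlags = field(default_factory=EvidenceFlags)
    source: str = "prediction"
    valid: bool = True

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt[0] < prev[1]:
                raise ValueError(f"overlapping exons in gene {self.id}")

    @property
    def is_mono_exonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (prev[1], nxt[0]) for prev, nxt in zip(self.exons, self.exons[1:])
        ]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class AlignmentRecord:
    """A transcript-to-genome alignment summary (identity and coverage as
    fractions of the query)."""

    query: str
    scaffold: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float


@dataclass
class VariantTable:
    """Biallelic diploid genotypes with population assignments.

    ``genotypes`` is a sites x samples int8 matrix of alternate-allele
    dosages (0, 1, 2) with -1 for missing. Positions are 1-based (VCF
    convention kept for this one container because every consumer speaks
    VCF coordinates).
    """

    scaffolds: list[str]
    positions: np.ndarray
    ref: list[str]
    alt: list[str]
    genotypes: np.ndarray
    samples: list[str]
    populations: dict[str, str] = field(default_factory=dict)
    skipped_multiallelic: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def population_indices(self) -> dict[str, np.ndarray]:
        """Sample column indices per population, in sorted population order."""
        pops: dict[str, list[int]] = {}
        for j, s in enumerate(self.samples):
            pops.setdefault(self.populations[s], []).append(j)
        return {p: np.array(ix) for p, ix in sorted(pops.items())}


@dataclass
class OrthogroupMatrix:
    """Family x species copy counts plus per-gene metadata.

    ``counts``: DataFrame indexed by family id with one integer column per
    species. ``gene_meta``: DataFrame indexed by gene id with columns
    family, species, length_aa, scaffold, start.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def genes_of(self, family: str, species: str) -> list[str]:
        m = self.gene_meta
        sel = (m["family"] == family) & (m["species"] == species)
        return list(m.index[sel])

    def validate(self) -> None:
        """Check that counts equal gene_index sizes where metadata exists."""
        if self.gene_meta.empty:
            return
        tab = (
            self.gene_meta.groupby(["family", "species"]).size().unstack(fill_value=0)
        )
        for fam in tab.index:
            for sp in tab.columns:
                if sp in self.counts.columns and fam in self.counts.index:
                    if int(tab.loc[fam, sp]) != int(self.counts.loc[fam, sp]):
                        raise ValueError(
                            f"count/gene_meta mismatch for {fam}/{sp}"
                        )
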