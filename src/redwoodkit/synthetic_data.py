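"""Seeded generators emulating every input the pipeline consumes.

Each generator is deterministic in (seed, config): the master seed fans
out to fixed per-generator substreams, so regenerating one data type never
perturbs another. Outputs carry ground-truth labels (planted intervals,
gene classes, family classes, tree scenarios, the Fst parameter), letting
every downstream stage be scored without external data.

What is emulated, at toy scale:
- scaffolds with terminal telomere arrays (tandem CCCT[A/C]AA), clustered
  copies of the 148-bp centromeric unit, N-gaps, and optional fused
  scaffolds joining two chromosomes (the split targets);
- a hexaploid 31-mer histogram: geometric error mass plus Poisson-shaped
  peaks at c, 2c, 3c with areas f1 G, f2 G/2, f3 G/3;
- a predicted gene set contaminated with structurally broken genes,
  softmasked retroelement ORFs, and processed pseudogenes;
- orthogroup matrices with planted species-specific / clade-absent /
  expanded / 3:1:1 / 2:1:1 / tandem families;
- gene trees under autopolyploid and allopolyploid scenarios, with
  optional NNI topological noise;
- biallelic genotypes under the Balding-Nichols model at a target Fst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    EvidenceFlags,
    GeneModel,
    IntervalRecord,
    KmerHistogram,
    OrthogroupMatrix,
    SequenceRecord,
    VariantTable,
    revcomp,
)
from .scaffold_curation import TELOMERE_MOTIFS, load_centromere_consensus

# fixed substream offsets: one per generator
_STREAM_SCAFFOLDS = 1
_STREAM_HISTOGRAM = 2
_STREAM_GENES = 3
_STREAM_ORTHO = 4
_STREAM_TREES = 5
_STREAM_VARIANTS = 6

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

STOP_CODONS = ("TAA", "TAG", "TGA")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases at the given per-base rate (never to the same base)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    hit = np.where(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# 1. scaffolds with planted telomeres / centromeres


@dataclass
class ScaffoldConfig:
    n_chromosomes: int = 3
    n_fused: int = 1  # extra scaffolds joining two chromosomes
    arm_length: int = 20_000
    telomere_copies: int = 30
    centromere_copies: int = 8  # tandem 148-bp copies per fragment
    centromere_fragments: int = 2  # fragments per centromeric cluster
    fragment_gap: int = 1_000  # bp between fragments (below merge distance)
    centromere_divergence: float = 0.03  # per-base substitution vs consensus
    n_gap_length: int = 50  # planted N-runs inside arms
    fused_spacer: int = 500

    def validate(self) -> None:
        if min(self.n_chromosomes, self.n_fused) < 0:
            raise ValueError("counts must be nonnegative")
        features = (
            2 * self.telomere_copies * 7
            + self.centromere_fragments * (self.centromere_copies * 148 + self.fragment_gap)
        )
        if self.arm_length < max(2 * self.n_gap_length + 100, 1000) or (
            2 * self.arm_length < features
        ):
            raise ValueError("arm_length too small for the planted features")


def _telomere_array(rng: np.random.Generator, copies: int) -> str:
    return "".join(str(rng.choice(TELOMERE_MOTIFS)) for _ in range(copies))


def _arm(rng: np.random.Generator, cfg: ScaffoldConfig) -> str:
    half = (cfg.arm_length - cfg.n_gap_length) // 2
    rest = cfg.arm_length - cfg.n_gap_length - half
    return _random_seq(rng, half) + "N" * cfg.n_gap_length + _random_seq(rng, rest)


def _chromosome(
    rng: np.random.Generator, cfg: ScaffoldConfig, consensus: str
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """One chromosome string plus feature tuples (start, end, kind, strand).

    Left telomere: C-rich motif forward ('+'); right telomere: reverse
    complement ('-'). The centromeric cluster sits between the two arms as
    ``centromere_fragments`` tandem-copy fragments.
    """
    parts: list[str] = []
    feats: list[tuple[int, int, str, str]] = []
    pos = 0

    def emit(seq: str, kind: str | None = None, strand: str = "+") -> None:
        nonlocal pos
        if kind:
            feats.append((pos, pos + len(seq), kind, strand))
        parts.append(seq)
        pos += len(seq)

    emit(_telomere_array(rng, cfg.telomere_copies), "telomere", "+")
    emit(_arm(rng, cfg))
    cluster_start = pos
    for i in range(cfg.centromere_fragments):
        if i:
            emit(_random_seq(rng, cfg.fragment_gap))
        fragment = "".join(
            _mutate(rng, consensus, cfg.centromere_divergence)
            for _ in range(cfg.centromere_copies)
        )
        emit(fragment, "centromere", "+")
    feats.append((cluster_start, pos, "centromere_region", "+"))
    emit(_arm(rng, cfg))
    emit(revcomp(_telomere_array(rng, cfg.telomere_copies)), "telomere", "-")
    return "".join(parts), feats


def gen_scaffolds(
    cfg: ScaffoldConfig, seed: int
) -> tuple[list[SequenceRecord], list[IntervalRecord]]:
    """Simulated scaffolds plus the truth intervals of planted features.

    The first ``n_chromosomes`` scaffolds are single chromosomes; the next
    ``n_fused`` are mis-joins of two chromosomes separated by a short
    spacer, leaving two centromeric regions and two internal, outward-
    facing telomere arrays on one scaffold.
    """
    cfg.validate()
    rng = _rng(seed, _STREAM_SCAFFOLDS)
    consensus = load_centromere_consensus()
    records: list[SequenceRecord] = []
    truth: list[IntervalRecord] = []

    def add(name: str, seq: str, feats: list[tuple[int, int, str, str]]) -> None:
        records.append(SequenceRecord(name, seq))
        for s, e, kind, strand in feats:
            truth.append(IntervalRecord(name, s, e, strand, kind))

    for i in range(cfg.n_chromosomes):
        seq, feats = _chromosome(rng, cfg, consensus)
        add(f"scaffold_{i + 1}", seq, feats)
    for i in range(cfg.n_fused):
        seq_a, feats_a = _chromosome(rng, cfg, consensus)
        seq_b, feats_b = _chromosome(rng, cfg, consensus)
        spacer = _random_seq(rng, cfg.fused_spacer)
        offset = len(seq_a) + len(spacer)
        feats = feats_a + [(s + offset, e + offset, k, st) for s, e, k, st in feats_b]
        add(f"fused_{i + 1}", seq_a + spacer + seq_b, feats)
    return records, truth


# ---------------------------------------------------------------------------
# 2. hexaploid k-mer histogram


@dataclass
class HistogramConfig:
    genome_size: int = 10_000_000  # haploid G in bp (toy scale)
    peak_coverage: int = 57  # per-copy depth c
    sharing_fractions: tuple[float, float, float] = (0.6, 0.25, 0.15)
    error_count0: float | None = None  # defaults to G
    error_decay: float = 0.7
    overdispersion: float = 1.0  # 1 = Poisson peaks; > 1 widens them
    max_coverage: int | None = None  # defaults to 4c

    def validate(self) -> None:
        if self.peak_coverage < 8:
            raise ValueError("peak coverage must be >= 8")
        f = self.sharing_fractions
        if any(x < 0 for x in f) or abs(sum(f) - 1) > 1e-9:
            raise ValueError("sharing fractions must be nonnegative and sum to 1")

    @property
    def expected_signal_instances(self) -> float:
        """Analytic k-mer instance mass of the signal: G x c."""
        return float(self.genome_size) * self.peak_coverage

    def expected_total_instances(self) -> float:
        e0 = self.genome_size if self.error_count0 is None else self.error_count0
        xmax = self.max_coverage or 4 * self.peak_coverage
        x = np.arange(1, xmax + 1)
        error = float(np.sum(e0 * self.error_decay ** (x - 1) * x))
        return error + self.expected_signal_instances


def gen_histogram(cfg: HistogramConfig, seed: int, k: int = 31) -> KmerHistogram:
    """Error mass plus three Poisson-shaped subgenome-sharing peaks.

    Component m in (1, 2, 3) holds f_m G / m distinct k-mers centered at
    coverage m c, so its instance mass is f_m G c; dividing the total
    instance mass above the error cutoff by c recovers G. Counts are
    rounded to integers with a small Poisson jitter so peak detection is
    not exact-arithmetic trivial.
    """
    cfg.validate()
    rng = _rng(seed, _STREAM_HISTOGRAM)
    c = cfg.peak_coverage
    xmax = cfg.max_coverage or 4 * c
    x = np.arange(1, xmax + 1)
    e0 = cfg.genome_size if cfg.error_count0 is None else cfg.error_count0
    counts = e0 * cfg.error_decay ** (x - 1)
    for m, f in zip((1, 2, 3), cfg.sharing_fractions):
        if f == 0:
            continue
        area = f * cfg.genome_size / m
        mu = m * c
        if cfg.overdispersion <= 1:
            pmf = stats.poisson.pmf(x, mu)
        else:
            # negative binomial with mean mu, variance mu * overdispersion
            p = 1 / cfg.overdispersion
            n = mu * p / (1 - p)
            pmf = stats.nbinom.pmf(x, n, p)
        counts = counts + area * pmf
    jitter = rng.normal(0, np.sqrt(np.maximum(counts, 1)) * 0.01)
    counts = np.rint(np.maximum(counts + jitter, 0)).astype(np.int64)
    keep = counts > 0
    return KmerHistogram(k=k, coverages=x[keep], counts=counts[keep])


# ---------------------------------------------------------------------------
# 3. gene models with planted contamination


@dataclass
class GeneModelConfig:
    n_valid_multi: int = 12
    n_valid_mono: int = 3  # unique mono-exonic genes (must survive)
    n_broken: int = 6  # cycled over intron/CDS-length/stop defects
    n_retro: int = 5
    n_pseudo: int = 5
    pseudo_identity: float = 0.80  # protein identity of pseudogene copies
    retro_mask_fraction: float = 0.85
    min_codons: int = 110
    max_codons: int = 220
    intergenic: int = 300
    scaffold_name: str = "sim_genes_1"

    def validate(self) -> None:
        if min(
            self.n_valid_multi, self.n_valid_mono, self.n_broken, self.n_retro, self.n_pseudo
        ) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_pseudo > 0 and self.n_valid_multi == 0:
            raise ValueError("pseudogenes need multi-exonic parents")


_AA_CODON = {}
for _codon in [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]:
    from Bio.Seq import Seq as _Seq

    _aa = str(_Seq(_codon).translate())
    _AA_CODON.setdefault(_aa, []).append(_codon)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop."""
    body = []
    for _ in range(n_codons - 2):
        while True:
            codon = _random_seq(rng, 3)
            if codon not in STOP_CODONS:
                break
        body.append(codon)
    return "ATG" + "".join(body) + str(rng.choice(STOP_CODONS))


def _mutate_protein_level(
    rng: np.random.Generator, cds: str, target_identity: float
) -> str:
    """Swap codons to different amino acids in a fraction of positions."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n_mut = round((1 - target_identity) * (len(codons) - 2))
    sites = rng.choice(np.arange(1, len(codons) - 1), size=n_mut, replace=False)
    from Bio.Seq import Seq

    for i in sites:
        old_aa = str(Seq(codons[i]).translate())
        while True:
            new_aa = str(rng.choice([a for a in _AA_CODON if a not in ("*", old_aa)]))
            break
        codons[i] = str(rng.choice(_AA_CODON[new_aa]))
    return "".join(codons)


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate()).rstrip("*")


class _GenomeBuilder:
    def __init__(self, scaffold: str, rng: np.random.Generator, intergenic: int):
        self.scaffold = scaffold
        self.rng = rng
        self.intergenic = intergenic
        self.parts: list[str] = []
        self.pos = 0

    def spacer(self) -> None:
        self.parts.append(_random_seq(self.rng, self.intergenic))
        self.pos += self.intergenic

    def place(self, pieces: list[tuple[str, bool]]) -> list[tuple[int, int]]:
        """Append (sequence, is_exon) pieces; return exon intervals."""
        exons = []
        for seq, is_exon in pieces:
            if is_exon:
                exons.append((self.pos, self.pos + len(seq)))
            self.parts.append(seq)
            self.pos += len(seq)
        return exons

    def sequence(self) -> str:
        return "".join(self.parts)


def _split_cds(rng: np.random.Generator, cds: str, n_exons: int) -> list[str]:
    if n_exons == 1:
        return [cds]
    # exon boundaries at codon multiples, every piece >= 30 bp
    n_codons = len(cds) // 3
    while True:
        cuts = np.sort(rng.choice(np.arange(10, n_codons - 10), size=n_exons - 1, replace=False))
        bounds = [0, *(int(c) * 3 for c in cuts), len(cds)]
        if all(b - a >= 30 for a, b in zip(bounds, bounds[1:])):
            return [cds[a:b] for a, b in zip(bounds, bounds[1:])]


def gen_gene_models(
    cfg: GeneModelConfig, seed: int
) -> tuple[list[GeneModel], SequenceRecord, dict[str, str], dict[str, EvidenceFlags]]:
    """Gene models with truth classes, on one synthetic scaffold.

    Returns (models, genome scaffold record, truth class per gene id,
    evidence flags per gene id). Classes: valid_multi, valid_mono,
    broken_intron / broken_cds / broken_stop, retro, pseudo.
    """
    cfg.validate()
    rng = _rng(seed, _STREAM_GENES)
    builder = _GenomeBuilder(cfg.scaffold_name, rng, cfg.intergenic)
    models: list[GeneModel] = []
    truth: dict[str, str] = {}
    evidence: dict[str, EvidenceFlags] = {}
    parent_cds: list[str] = []

    def n_codons() -> int:
        return int(rng.integers(cfg.min_codons, cfg.max_codons + 1))

    def add_gene(
        gid: str,
        cls: str,
        exon_seqs: list[str],
        intron_len: int,
        cds_seq: str,
        ev: EvidenceFlags,
        mask: float = 0.0,
        lowercase: bool = False,
    ) -> None:
        builder.spacer()
        pieces: list[tuple[str, bool]] = []
        for i, ex in enumerate(exon_seqs):
            if i:
                pieces.append((_random_seq(rng, intron_len), False))
            if lowercase:
                # softmask the leading `mask` fraction of the exon so the
                # on-disk FASTA reproduces the recorded fraction
                k = round(mask * len(ex))
                ex = ex[:k].lower() + ex[k:]
            pieces.append((ex, True))
        exons = builder.place(pieces)
        model = GeneModel(
            id=gid,
            scaffold=cfg.scaffold_name,
            strand="+",
            exons=exons,
            cds=list(exons),
            protein=_translate(cds_seq) if len(cds_seq) % 3 == 0 else "",
            cds_seq=cds_seq,
            softmask_fraction=mask,
            evidence=ev,
        )
        models.append(model)
        truth[gid] = cls
        evidence[gid] = ev

    strong = EvidenceFlags(has_similarity_hit=True, domain_count=2, has_family_assignment=True)

    for i in range(cfg.n_valid_multi):
        cds = _random_cds(rng, n_codons())
        parent_cds.append(cds)
        exon_seqs = _split_cds(rng, cds, int(rng.integers(2, 5)))
        add_gene(f"valid_multi_{i + 1}", "valid_multi", exon_seqs, 60, cds, strong)

    for i in range(cfg.n_valid_mono):
        cds = _random_cds(rng, n_codons())
        add_gene(f"valid_mono_{i + 1}", "valid_mono", [cds], 0, cds, strong)

    defects = ("intron", "cds", "stop")
    for i in range(cfg.n_broken):
        defect = defects[i % 3]
        if defect == "intron":
            cds = _random_cds(rng, n_codons())
            exon_seqs = _split_cds(rng, cds, 2)
            add_gene(f"broken_{i + 1}", "broken_intron", exon_seqs, 8, cds, strong)
        elif defect == "cds":
            cds = _random_cds(rng, 32)  # 96 bp < 100
            add_gene(f"broken_{i + 1}", "broken_cds", [cds], 0, cds, strong)
        else:
            cds = _random_cds(rng, n_codons())[:-3] + "GGA"  # no stop
            add_gene(f"broken_{i + 1}", "broken_stop", [cds], 0, cds, strong)

    for i in range(cfg.n_retro):
        cds = _random_cds(rng, n_codons())
        ev = EvidenceFlags(
            has_similarity_hit=True, domain_count=1, retro_domain_flag=True
        )
        add_gene(
            f"retro_{i + 1}",
            "retro",
            [cds],
            0,
            cds,
            ev,
            mask=cfg.retro_mask_fraction,
            lowercase=True,
        )

    for i in range(cfg.n_pseudo):
        parent = parent_cds[int(rng.integers(0, len(parent_cds)))]
        cds = _mutate_protein_level(rng, parent, cfg.pseudo_identity)
        add_gene(f"pseudo_{i + 1}", "pseudo", [cds], 0, cds, strong)

    builder.spacer()
    genome = SequenceRecord(cfg.scaffold_name, builder.sequence())
    return models, genome, truth, evidence


# ---------------------------------------------------------------------------
# 4. orthogroup matrices


@dataclass
class OrthogroupConfig:
    focal: str = "CR"
    reference_species: tuple[str, str] = ("GS", "MG")
    clade_species: tuple[str, ...] = ("GS", "MG", "THPL")
    outgroup_species: tuple[str, ...] = ("PILA",)
    n_species_specific: int = 5
    n_absent_in_clade: int = 4
    n_expanded: int = 6
    n_contracted: int = 3
    n_three_to_one: int = 7
    n_two_to_one: int = 8
    n_tandem: int = 3  # 2:1:1 families whose focal copies sit in tandem
    n_short_member: int = 2  # 3:1:1 families failing the length filter
    n_background: int = 10
    tandem_span: int = 50_000
    scaffold_spacing: int = 1_000_000
    # members of multicopy families draw lengths from this band, whose lower
    # bound exceeds 0.75 x the upper bound so length filters pass by design
    length_range: tuple[int, int] = (400, 500)

    @property
    def all_species(self) -> list[str]:
        seen = dict.fromkeys(
            [self.focal, *self.reference_species, *self.clade_species, *self.outgroup_species]
        )
        return list(seen)


def gen_orthogroups(
    cfg: OrthogroupConfig, seed: int
) -> tuple[OrthogroupMatrix, dict[str, set[str]]]:
    """Orthogroup matrix with planted copy-number classes and truth sets.

    Truth keys mirror the classifier semantics: ``three_to_one`` includes
    every family with focal=3 and refs=1 (even length-filter failures);
    ``tandem`` marks families whose focal members lie within
    ``tandem_span`` on one scaffold; ``phylo_pass`` is the subset of
    multicopy families passing the length rules and tandem exclusion, by
    construction.
    """
    rng = _rng(seed, _STREAM_ORTHO)
    species = cfg.all_species
    refs = list(cfg.reference_species)
    rows: list[dict[str, int]] = []
    fam_ids: list[str] = []
    meta_rows: list[dict[str, object]] = []
    truth: dict[str, set[str]] = {
        k: set()
        for k in (
            "species_specific",
            "absent_in_clade",
            "expanded",
            "contracted",
            "three_to_one",
            "two_to_one",
            "tandem",
            "phylo_pass",
        )
    }
    fam_counter = 0

    def lengths(n: int, short: bool = False) -> list[int]:
        lo, hi = cfg.length_range
        vals = [int(rng.integers(lo, hi + 1)) for _ in range(n)]
        if short and vals:
            vals[-1] = int(rng.integers(100, 230))  # fails >300 aa and 75%-of-max
        return vals

    def add_family(
        counts: dict[str, int],
        classes: tuple[str, ...],
        tandem: bool = False,
        short_member: bool = False,
    ) -> None:
        nonlocal fam_counter
        fam_counter += 1
        fam = f"OG{fam_counter:05d}"
        fam_ids.append(fam)
        rows.append({sp: counts.get(sp, 0) for sp in species})
        member_lengths = lengths(sum(counts.values()), short=short_member)
        li = 0
        for sp in species:
            for k in range(counts.get(sp, 0)):
                if sp == cfg.focal and tandem and k > 0:
                    scaffold = f"{cfg.focal}_sc{fam_counter}"
                    start = 10_000 + int(rng.integers(1, cfg.tandem_span - 10_000))
                elif sp == cfg.focal:
                    scaffold = f"{cfg.focal}_sc{fam_counter}" if tandem else f"{cfg.focal}_sc{fam_counter}_{k}"
                    start = 10_000 if tandem else int(rng.integers(0, cfg.scaffold_spacing))
                else:
                    scaffold = f"{sp}_sc{fam_counter}_{k}"
                    start = int(rng.integers(0, cfg.scaffold_spacing))
                meta_rows.append(
                    {
                        "gene": f"{fam}_{sp}_{k + 1}",
                        "family": fam,
                        "species": sp,
                        "length_aa": member_lengths[li],
                        "scaffold": scaffold,
                        "start": start,
                    }
                )
                li += 1
        for cls in classes:
            truth[cls].add(fam)
        # expansion/contraction truth follows from the planted counts by the
        # fold rule itself (e.g. a 3:1:1 family IS a 2-fold expansion), so it
        # is derived here for every family rather than planted per class
        others_present = [
            counts.get(sp, 0) for sp in species if sp != cfg.focal and counts.get(sp, 0) > 0
        ]
        n_focal = counts.get(cfg.focal, 0)
        if n_focal > 0 and others_present:
            baseline = sum(others_present) / len(others_present)
            if n_focal >= 2 * baseline:
                truth["expanded"].add(fam)
            elif n_focal <= baseline / 2:
                truth["contracted"].add(fam)

    ref_one = {r: 1 for r in refs}
    others_one = {sp: 1 for sp in species if sp != cfg.focal}

    # species-specific families are by definition also absent from the clade
    for _ in range(cfg.n_species_specific):
        add_family(
            {cfg.focal: int(rng.integers(2, 5))},
            ("species_specific", "absent_in_clade"),
        )
    for _ in range(cfg.n_absent_in_clade):
        counts = {cfg.focal: int(rng.integers(1, 4))}
        for sp in cfg.outgroup_species:
            counts[sp] = int(rng.integers(1, 3))
        add_family(counts, ("absent_in_clade",))
    for _ in range(cfg.n_expanded):
        base = int(rng.integers(2, 5))
        counts = {sp: base for sp in species if sp != cfg.focal}
        counts[cfg.focal] = 2 * base + int(rng.integers(0, 3))
        add_family(counts, ())
    for _ in range(cfg.n_contracted):
        counts = {sp: 4 for sp in species if sp != cfg.focal}
        counts[cfg.focal] = 1
        add_family(counts, ())
    for i in range(cfg.n_three_to_one):
        short = i < cfg.n_short_member
        counts = {cfg.focal: 3, **ref_one}
        classes = ["three_to_one"]
        if not short:
            classes.append("phylo_pass")
        add_family(counts, tuple(classes), short_member=short)
    for _ in range(cfg.n_two_to_one):
        add_family({cfg.focal: 2, **ref_one}, ("two_to_one", "phylo_pass"))
    for _ in range(cfg.n_tandem):
        add_family(
            {cfg.focal: 2, **ref_one}, ("two_to_one", "tandem"), tandem=True
        )
    for _ in range(cfg.n_background):
        add_family({cfg.focal: 1, **others_one}, ())

    counts_df = pd.DataFrame(rows, index=fam_ids)[species].astype(int)
    counts_df.index.name = "family"
    meta_df = pd.DataFrame(meta_rows).set_index("gene")
    return OrthogroupMatrix(counts=counts_df, gene_meta=meta_df), truth


# ---------------------------------------------------------------------------
# 5. gene trees under ploidy-origin scenarios


@dataclass
class GeneTreeConfig:
    n_trees: int = 50
    focal: str = "CR"
    sisters: tuple[str, str] = ("GS", "MG")
    outgroup: str = "OUT"
    focal_copies: int | None = None  # None = alternate 2 and 3
    sister_choice: str = "GS"  # sister lineage under the auto scenario
    nni_moves: int = 0  # topological noise per tree

    def validate(self) -> None:
        if self.n_trees < 0 or self.nni_moves < 0:
            raise ValueError("counts must be nonnegative")
        if self.sister_choice not in self.sisters:
            raise ValueError("sister_choice must be one of sisters")


def _auto_newick(copies: list[str], sis: str, other: str, outgroup: str) -> str:
    """Focal copies as a nested clade, sister lineage ``sis`` outside it."""
    clade = copies[0]
    for c in copies[1:]:
        clade = f"({clade},{c})"
    return f"((({clade},{sis}_1),{other}_1),{outgroup}_1);"


def _allo_newick(copies: list[str], donor: str, other: str, outgroup: str) -> str:
    # one focal copy attaches inside the donor lineage
    rest = copies[1]
    if len(copies) == 3:
        rest = f"({copies[1]},{copies[2]})"
    return f"(((({copies[0]},{donor}_1),{rest}),{other}_1),{outgroup}_1);"


def _apply_nni(tree: dendropy.Tree, rng: np.random.Generator, moves: int) -> None:
    for _ in range(moves):
        internal = [
            e
            for e in tree.preorder_edge_iter()
            if e.head_node is not None
            and e.tail_node is not None
            and not e.head_node.is_leaf()
            and e.tail_node.parent_node is not None
        ]
        if not internal:
            return
        edge = internal[int(rng.integers(0, len(internal)))]
        head, tail = edge.head_node, edge.tail_node
        head_children = head.child_nodes()
        siblings = [c for c in tail.child_nodes() if c is not head]
        if not head_children or not siblings:
            continue
        a = head_children[int(rng.integers(0, len(head_children)))]
        b = siblings[int(rng.integers(0, len(siblings)))]
        head.remove_child(a)
        tail.remove_child(b)
        head.add_child(b)
        tail.add_child(a)


def gen_gene_trees(cfg: GeneTreeConfig, seed: int, scenario: str = "auto") -> list[str]:
    """Newick strings under a ploidy-origin scenario.

    ``auto``: focal copies form a clade sister to ``sister_choice``.
    ``allo_GS`` / ``allo_MG``: one focal copy branches inside that donor
    lineage, breaking focal monophyly. ``nni_moves`` random NNI
    rearrangements per tree add topological noise.
    """
    cfg.validate()
    if scenario not in ("auto", "allo_GS", "allo_MG"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = _rng(seed, _STREAM_TREES)
    sis_a, sis_b = cfg.sisters
    out: list[str] = []
    for t in range(cfg.n_trees):
        ncopies = cfg.focal_copies or (2 + t % 2)
        copies = [f"{cfg.focal}_{i + 1}" for i in range(ncopies)]
        if scenario == "auto":
            sis = cfg.sister_choice
            other = sis_b if sis == sis_a else sis_a
            nwk = _auto_newick(copies, sis, other, cfg.outgroup)
        else:
            donor = scenario.split("_", 1)[1]
            other = sis_b if donor == sis_a else sis_a
            nwk = _allo_newick(copies, donor, other, cfg.outgroup)
        if cfg.nni_moves:
            tree = dendropy.Tree.get(
                data=nwk, schema="newick", preserve_underscores=True
            )
            _apply_nni(tree, rng, cfg.nni_moves)
            nwk = (
                tree.as_string(schema="newick", suppress_rooting=True).strip()
            )
        out.append(nwk)
    return out


# ---------------------------------------------------------------------------
# 6. Balding-Nichols genotypes


@dataclass
class VariantConfig:
    n_populations: int = 2
    n_diploids_per_pop: int = 30
    n_loci: int = 20_000
    fst: float = 0.05
    scaffold_length: int = 2_000_000
    scaffold_name: str = "sim_sc1"
    p_min: float = 0.05
    p_max: float = 0.95

    def validate(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if min(self.n_populations, self.n_diploids_per_pop, self.n_loci) < 1:
            raise ValueError("populations, samples and loci must be positive")
        if self.n_loci > self.scaffold_length:
            raise ValueError("more loci than scaffold positions")


def gen_variants(cfg: VariantConfig, seed: int) -> VariantTable:
    """Genotypes under the Balding-Nichols model at drift parameter F.

    Each locus draws an ancestral frequency p ~ U(p_min, p_max); each
    population draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F);
    diploid dosages are Binomial(2, population frequency). Monomorphic
    draws are kept — they carry no Fst information but are legitimate
    output of the model.
    """
    cfg.validate()
    rng = _rng(seed, _STREAM_VARIANTS)
    f = cfg.fst
    positions = np.sort(
        rng.choice(np.arange(1, cfg.scaffold_length + 1), size=cfg.n_loci, replace=False)
    )
    p_anc = rng.uniform(cfg.p_min, cfg.p_max, cfg.n_loci)
    shape = (1 - f) / f
    geno = np.empty((cfg.n_loci, cfg.n_populations * cfg.n_diploids_per_pop), dtype=np.int8)
    populations: dict[str, str] = {}
    samples: list[str] = []
    for pop in range(cfg.n_populations):
        pf = rng.beta(p_anc * shape, (1 - p_anc) * shape)
        block = rng.binomial(2, pf[:, None], (cfg.n_loci, cfg.n_diploids_per_pop))
        lo = pop * cfg.n_diploids_per_pop
        geno[:, lo : lo + cfg.n_diploids_per_pop] = block
        for k in range(cfg.n_diploids_per_pop):
            name = f"pop{pop + 1}_ind{k + 1}"
            samples.append(name)
            populations[name] = f"pop{pop + 1}"
    return VariantTable(
        scaffolds=[cfg.scaffold_name] * cfg.n_loci,
        positions=positions,
        ref=["A"] * cfg.n_loci,
        alt=["G"] * cfg.n_loci,
        genotypes=geno,
        samples=samples,
        populations=populations,
    )


# ---------------------------------------------------------------------------
# master config


@dataclass
class SimulationConfig:
    """One seed, one block per generator; same (seed, config) in, same
    bytes out — per-generator substreams are derived by fixed offsets."""

    seed: int = 0
    scaffolds: ScaffoldConfig = field(default_factory=ScaffoldConfig)
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    genes: GeneModelConfig = field(default_factory=GeneModelConfig)
    orthogroups: OrthogroupConfig = field(default_factory=OrthogroupConfig)
    trees: GeneTreeConfig = field(default_factory=GeneTreeConfig)
    variants: VariantConfig = field(default_factory=VariantConfig)
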