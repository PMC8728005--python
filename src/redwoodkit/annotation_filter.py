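"""Staged reduction of an inflated predicted gene set.

Ab initio prediction in a huge, repeat-rich polyploid genome massively
over-calls genes: fragments, retroelement ORFs, and processed pseudogenes
dominate the raw set. The pipeline applies, in fixed order:

1. structural filter  — complete ORF, exon/intron >= 9 bp, CDS >= 100 bp;
2. functional filter  — keep a gene showing any of: a similarity hit, at
   least one protein domain, or a gene-family assignment;
3. retroelement filter — remove genes that are BOTH flagged with a
   retroelement domain AND at least 70% softmasked;
4. mono-exonic filter — remove mono-exonic genes whose protein matches a
   multi-exonic protein at >= 75% identity over >= 70% of their own
   length (processed-pseudogene signature);
5. overlap resolution — where prediction and transcriptome-derived models
   overlap in CDS on the same strand, the transcriptome model wins.

Each stage reconciles exactly: removed + retained = input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .core import AlignmentRecord, GeneModel

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"

DEFAULT_MASK_THRESHOLD = 0.70
DEFAULT_MONO_MIN_IDENTITY = 0.75
DEFAULT_MONO_MIN_COVERAGE = 0.70
DEFAULT_EVIDENCE_MIN_IDENTITY = 0.95
DEFAULT_EVIDENCE_MIN_COVERAGE = 0.95


@dataclass
class FilterReport:
    rule: str
    n_input: int = 0
    reasons: dict[str, str] = field(default_factory=dict)  # gene id -> reason
    extra: dict[str, object] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.reasons)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


# ---------------------------------------------------------------------------
# 1. structural


def _structural_reason(m: GeneModel) -> str | None:
    if not m.cds:
        return "no_cds"
    if m.cds_length < 100:
        return "cds_lt_100"
    if m.cds_length % 3 != 0:
        return "cds_not_multiple_of_3"
    for s, e in m.exons:
        if e - s < 9:
            return "exon_lt_9"
    for s, e in m.introns:
        if e - s < 9:
            return "intron_lt_9"
    if m.cds_seq:
        seq = m.cds_seq.upper()
        if not seq.startswith(START_CODON):
            return "missing_start"
        if seq[-3:] not in STOP_CODONS:
            return "missing_stop"
        internal = {seq[i : i + 3] for i in range(0, len(seq) - 3, 3)}
        if internal & STOP_CODONS:
            return "internal_stop"
    elif m.protein:
        if not m.protein.startswith("M"):
            return "missing_start"
        if "*" in m.protein.rstrip("*"):
            return "internal_stop"
    return None


def structural_filter(models: list[GeneModel]) -> tuple[list[GeneModel], FilterReport]:
    report = FilterReport("structural", n_input=len(models))
    passing = []
    for m in models:
        reason = _structural_reason(m)
        if reason is None:
            passing.append(m)
        else:
            report.reasons[m.id] = reason
    return passing, report


# ---------------------------------------------------------------------------
# 2. functional evidence


def functional_filter(models: list[GeneModel]) -> tuple[list[GeneModel], FilterReport]:
    """Discard models lacking every kind of functional evidence."""
    report = FilterReport("functional", n_input=len(models))
    passing = []
    for m in models:
        ev = m.evidence
        if ev.has_similarity_hit or ev.domain_count >= 1 or ev.has_family_assignment:
            passing.append(m)
        else:
            report.reasons[m.id] = "no_functional_evidence"
    return passing, report


# ---------------------------------------------------------------------------
# 3. retroelement


def retroelement_filter(
    models: list[GeneModel], mask_threshold: float = DEFAULT_MASK_THRESHOLD
) -> tuple[list[GeneModel], FilterReport]:
    """Remove retro-domain-flagged genes that are >= 70% softmasked.

    Both conditions are required; the 70% boundary is inclusive.
    """
    report = FilterReport("retroelement", n_input=len(models))
    passing = []
    for m in models:
        if m.evidence.retro_domain_flag and m.softmask_fraction >= mask_threshold:
            report.reasons[m.id] = "retroelement_masked"
        else:
            passing.append(m)
    return passing, report


# ---------------------------------------------------------------------------
# 4. mono-exonic vs multi-exonic proteins

_aligner = Align.PairwiseAligner(
    mode="local",
    match_score=2,
    mismatch_score=-1,
    open_gap_score=-5,
    extend_gap_score=-0.5,
)


def _kmers(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def best_protein_hit(query: str, targets: dict[str, str]) -> tuple[str, float, float] | None:
    """Best local-alignment hit of ``query`` among ``targets``.

    Candidate targets are seeded by shared 4-mers, then aligned; returns
    (target id, identity, coverage) where identity = matches / aligned
    columns and coverage = aligned query residues / query length.
    """
    qk = _kmers(query)
    best: tuple[str, float, float] | None = None
    for name, target in targets.items():
        if not target or len(qk & _kmers(target)) < 2:
            continue
        alns = _aligner.align(query, target)
        if len(alns) == 0:
            continue
        aln = alns[0]
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        if columns == 0:
            continue
        identity = counts.identities / columns
        q_aligned = sum(e - s for s, e in aln.aligned[0])
        coverage = q_aligned / len(query)
        if best is None or identity * coverage > best[1] * best[2]:
            best = (name, identity, coverage)
    return best


def monoexonic_filter(
    models: list[GeneModel],
    min_identity: float = DEFAULT_MONO_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MONO_MIN_COVERAGE,
    keep_matches: bool = False,
) -> tuple[list[GeneModel], FilterReport]:
    """Align mono-exonic proteins to multi-exonic proteins.

    A mono-exonic model matching any multi-exonic protein at
    >= ``min_identity`` over >= ``min_coverage`` of its own length is a
    putative processed pseudogene and is removed (or kept, with every
    non-matching mono-exonic removed instead, when ``keep_matches`` —
    the alternative reading of the protocol — is on).
    """
    report = FilterReport("monoexonic", n_input=len(models))
    multi = {m.id: m.protein for m in models if not m.is_mono_exonic and m.protein}
    if not multi:
        report.extra["warning"] = "no multi-exonic proteins; mono-exonics retained"
        return list(models), report
    passing: list[GeneModel] = []
    best_hits: dict[str, tuple[str, float, float]] = {}
    for m in models:
        if not m.is_mono_exonic:
            passing.append(m)
            continue
        hit = best_protein_hit(m.protein, multi) if m.protein else None
        if hit:
            best_hits[m.id] = hit
        matches = (
            hit is not None and hit[1] >= min_identity and hit[2] >= min_coverage
        )
        removed = (matches and not keep_matches) or (not matches and keep_matches)
        if removed:
            report.reasons[m.id] = (
                "processed_pseudogene" if matches else "unsupported_monoexonic"
            )
        else:
            passing.append(m)
    report.extra["best_hits"] = best_hits
    return passing, report


# ---------------------------------------------------------------------------
# transcript alignment evidence


def alignment_evidence_filter(
    records: list[AlignmentRecord],
    min_identity: float = DEFAULT_EVIDENCE_MIN_IDENTITY,
    min_coverage: float = DEFAULT_EVIDENCE_MIN_COVERAGE,
) -> list[AlignmentRecord]:
    """Keep transcript-to-genome alignments at >= 0.95 identity AND coverage
    (both thresholds inclusive)."""
    return [
        r for r in records if r.identity >= min_identity and r.coverage >= min_coverage
    ]


# ---------------------------------------------------------------------------
# 5. overlap resolution


def _cds_overlap(a: GeneModel, b: GeneModel) -> bool:
    if a.scaffold != b.scaffold or a.strand != b.strand:
        return False
    for s1, e1 in a.cds:
        for s2, e2 in b.cds:
            if s1 < e2 and s2 < e1:
                return True
    return False


def resolve_overlaps(
    prediction_models: list[GeneModel],
    transcriptome_models: list[GeneModel],
) -> tuple[list[GeneModel], FilterReport]:
    """Transcriptome-derived models take precedence over predictions that
    overlap them in CDS on the same strand; everything else passes."""
    report = FilterReport(
        "overlap_resolution",
        n_input=len(prediction_models) + len(transcriptome_models),
    )
    by_scaffold: dict[str, list[GeneModel]] = {}
    for t in transcriptome_models:
        by_scaffold.setdefault(t.scaffold, []).append(t)
    merged: list[GeneModel] = []
    for p in prediction_models:
        if any(_cds_overlap(p, t) for t in by_scaffold.get(p.scaffold, [])):
            report.reasons[p.id] = "superseded_by_transcriptome"
        else:
            merged.append(p)
    merged.extend(transcriptome_models)
    return merged, report


# ---------------------------------------------------------------------------
# full pipeline


def run_filter_pipeline(
    prediction_models: list[GeneModel],
    transcriptome_models: list[GeneModel] | None = None,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
    mono_min_identity: float = DEFAULT_MONO_MIN_IDENTITY,
    mono_min_coverage: float = DEFAULT_MONO_MIN_COVERAGE,
    keep_monoexonic_matches: bool = False,
) -> tuple[list[GeneModel], list[FilterReport]]:
    """Apply the filter stages in their fixed order and collect reports."""
    reports: list[FilterReport] = []
    models, rep = structural_filter(prediction_models)
    reports.append(rep)
    models, rep = functional_filter(models)
    reports.append(rep)
    models, rep = retroelement_filter(models, mask_threshold)
    reports.append(rep)
    models, rep = monoexonic_filter(
        models, mono_min_identity, mono_min_coverage, keep_monoexonic_matches
    )
    reports.append(rep)
    if transcriptome_models:
        trans, rep_t = structural_filter(transcriptome_models)
        rep_t.rule = "structural_transcriptome"
        reports.append(rep_t)
        models, rep = resolve_overlaps(models, trans)
        reports.append(rep)
    return models, reports


def report_table(reports: list[FilterReport]) -> str:
    """TSV rendering of per-rule removed/retained counts."""
    lines = ["rule\tn_input\tn_removed\tn_retained"]
    for r in reports:
        lines.append(f"{r.rule}\t{r.n_input}\t{r.n_removed}\t{r.n_retained}")
    return "\n".join(lines) + "\n"
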