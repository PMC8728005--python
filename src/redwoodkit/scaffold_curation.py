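"""Telomere/centromere detection, scaffold splitting, and assembly stats.

Chromosome-scale scaffolds in the curated assembly carry terminal telomere
arrays (tandem copies of the degenerate unit CCCT[A/C]AA) and a single
centromeric region (a cluster of copies of a 148-bp tandem repeat). A
scaffold holding two centromeric regions is a mis-join of two chromosomes;
it is split between the regions, preferentially at internal telomere
arrays whose orientation marks them as chromosome ends.

Orientation convention: a '+' telomere hit means the C-rich strand of the
motif reads forward, which marks a chromosome 5' (left) end; a '-' hit
(G-rich forward) marks a 3' (right) end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .core import SequenceRecord, revcomp

TELOMERE_MOTIFS = ("CCCTAAA", "CCCTCAA")

# curation defaults (tool thresholds; the upstream protocol names the
# search tools but not their cutoffs, so these are surfaced in config)
DEFAULT_MIN_ARRAY_BP = 100
DEFAULT_MAX_MISMATCH_FRAC = 0.1
DEFAULT_MIN_IDENTITY = 0.8
DEFAULT_MIN_HIT_BP = 100
DEFAULT_MERGE_DISTANCE = 250_000
DEFAULT_END_WINDOW = 1_000
DEFAULT_CONTIG_GAP_MIN = 10


@dataclass
class RepeatHit:
    scaffold: str
    start: int
    end: int
    kind: str  # telomere | centromere
    orientation: str  # '+' or '-' (telomere: strand of the C-rich motif)
    identity: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CentromericRegion:
    scaffold: str
    start: int
    end: int
    copy_count: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AssemblyStats:
    total_bp: int
    n_scaffolds: int
    n_contigs: int
    scaffold_n50: int
    contig_n50: int
    scaffold_ng50: int | None = None
    contig_ng50: int | None = None


def load_centromere_consensus() -> str:
    """The bundled 148-bp centromeric repeat unit."""
    text = (
        resources.files("redwoodkit").joinpath("data/centromere_consensus.fasta")
    ).read_text()
    seq = "".join(l.strip() for l in text.splitlines() if not l.startswith(">"))
    return seq.upper()


# ---------------------------------------------------------------------------
# Telomere scan


def _chain_motif_runs(
    seq_u: str,
    scaffold: str,
    motifs: tuple[str, ...],
    orientation: str,
    min_array_bp: int,
    max_mismatch_frac: float,
) -> list[RepeatHit]:
    unit = len(motifs[0])
    pattern = re.compile("|".join(motifs))
    occ = [(m.start(), m.end()) for m in pattern.finditer(seq_u)]
    hits: list[RepeatHit] = []
    i = 0
    while i < len(occ):
        run_start, run_end = occ[i]
        matched = unit
        j = i + 1
        # chain occurrences, tolerating up to one corrupted unit between
        while j < len(occ) and occ[j][0] - run_end <= unit:
            span = occ[j][1] - run_start
            mism = span - (matched + unit)
            if mism / span > max_mismatch_frac:
                break
            run_end = occ[j][1]
            matched += unit
            j += 1
        span = run_end - run_start
        if span >= min_array_bp:
            hits.append(
                RepeatHit(
                    scaffold, run_start, run_end, "telomere", orientation, matched / span
                )
            )
        i = j
    return hits


def scan_telomeres(
    record: SequenceRecord,
    min_array_bp: int = DEFAULT_MIN_ARRAY_BP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> list[RepeatHit]:
    """Maximal tandem telomere-motif arrays on both strands.

    Exact motif copies (either degenerate variant) are chained into runs;
    bases between chained copies count as mismatches, bounded by
    ``max_mismatch_frac`` of the run span. Runs shorter than
    ``min_array_bp`` are dropped.
    """
    seq_u = record.sequence.upper()
    fwd = _chain_motif_runs(
        seq_u, record.id, TELOMERE_MOTIFS, "+", min_array_bp, max_mismatch_frac
    )
    rev_motifs = tuple(revcomp(m).upper() for m in TELOMERE_MOTIFS)
    rev = _chain_motif_runs(
        seq_u, record.id, rev_motifs, "-", min_array_bp, max_mismatch_frac
    )
    return sorted(fwd + rev, key=lambda h: h.start)


# ---------------------------------------------------------------------------
# Centromere scan

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(seq), 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def _window_identities(seq_code: np.ndarray, cons_code: np.ndarray) -> np.ndarray:
    """Identity of the ungapped consensus alignment at every window offset."""
    n, m = len(seq_code), len(cons_code)
    if n < m:
        return np.zeros(0)
    matches = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        matches += seq_code[j : j + n - m + 1] == cons_code[j]
    return matches / m


def scan_centromeres(
    record: SequenceRecord,
    consensus: str | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_hit_bp: int = DEFAULT_MIN_HIT_BP,
) -> list[RepeatHit]:
    """Ungapped sliding-window matches of the 148-bp unit, both strands.

    Windows at identity >= ``min_identity`` are merged into maximal hits
    (recording the best window identity); merged hits shorter than
    ``min_hit_bp`` are dropped.
    """
    if consensus is None:
        consensus = load_centromere_consensus()
    if len(consensus) != 148:
        raise ValueError(f"centromere consensus must be 148 bp, got {len(consensus)}")
    seq_code = _encode(record.sequence)
    m = len(consensus)
    windows: list[tuple[int, float, str]] = []
    for cons, orient in ((consensus, "+"), (revcomp(consensus), "-")):
        ident = _window_identities(seq_code, _encode(cons))
        for i in np.where(ident >= min_identity)[0]:
            windows.append((int(i), float(ident[i]), orient))
    windows.sort()
    hits: list[RepeatHit] = []
    for start, ident, orient in windows:
        if hits and start <= hits[-1].end:
            last = hits[-1]
            last.end = max(last.end, start + m)
            if ident > last.identity:
                last.identity = ident
                last.orientation = orient
        else:
            hits.append(
                RepeatHit(record.id, start, start + m, "centromere", orient, ident)
            )
    return [h for h in hits if len(h) >= min_hit_bp]


# ---------------------------------------------------------------------------
# Merging and splitting


def merge_centromeric_hits(
    hits: list[RepeatHit], merge_distance: int = DEFAULT_MERGE_DISTANCE
) -> list[CentromericRegion]:
    """Single-linkage merge of centromere hits separated by < merge_distance.

    The gap is measured between hit envelopes (next.start - prev.end) and
    the threshold is strict: a gap of exactly ``merge_distance`` separates.
    """
    by_scaffold: dict[str, list[RepeatHit]] = {}
    for h in hits:
        if h.kind != "centromere":
            continue
        by_scaffold.setdefault(h.scaffold, []).append(h)
    regions: list[CentromericRegion] = []
    for scaffold in sorted(by_scaffold):
        shits = sorted(by_scaffold[scaffold], key=lambda h: (h.start, h.end))
        cur: CentromericRegion | None = None
        for h in shits:
            if cur is not None and h.start - cur.end < merge_distance:
                cur.end = max(cur.end, h.end)
                cur.copy_count += 1
            else:
                cur = CentromericRegion(scaffold, h.start, h.end, 1)
                regions.append(cur)
    return regions


@dataclass
class SplitEvent:
    scaffold: str
    position: int
    reason: str  # telomere | gap | unresolved


def _n_gaps(seq: str, lo: int, hi: int, min_len: int = 1) -> list[tuple[int, int]]:
    return [
        (m.start() + lo, m.end() + lo)
        for m in re.finditer(r"[Nn]+", seq[lo:hi])
        if m.end() - m.start() >= min_len
    ]


def split_scaffolds(
    scaffolds: list[SequenceRecord],
    regions: list[CentromericRegion],
    telomere_hits: list[RepeatHit],
) -> tuple[list[SequenceRecord], list[SplitEvent]]:
    """Split every scaffold holding more than one centromeric region.

    Between each consecutive region pair: (a) internal telomere arrays
    whose orientation faces the nearer centromere mark chromosome ends; the
    scaffold is split at each such array's boundary distal to that
    centromere (the telomere stays with its arm). (b) With no qualifying
    telomere, the split falls at the midpoint of the largest N-gap between
    the regions. (c) With neither, the pair is flagged unresolved and left
    joined. Concatenating the output pieces reproduces the input exactly.
    """
    regions_by_sc: dict[str, list[CentromericRegion]] = {}
    for r in regions:
        regions_by_sc.setdefault(r.scaffold, []).append(r)
    tel_by_sc: dict[str, list[RepeatHit]] = {}
    for t in telomere_hits:
        tel_by_sc.setdefault(t.scaffold, []).append(t)

    out: list[SequenceRecord] = []
    events: list[SplitEvent] = []
    for rec in scaffolds:
        regs = sorted(regions_by_sc.get(rec.id, []), key=lambda r: r.start)
        cuts: list[tuple[int, str]] = []
        for left, right in zip(regs, regs[1:]):
            pair_cuts: list[tuple[int, str]] = []
            for tel in tel_by_sc.get(rec.id, []):
                if not (left.end <= tel.start and tel.end <= right.start):
                    continue
                nearer_left = (tel.start - left.end) <= (right.start - tel.end)
                # '-' arrays (G-rich forward) end a chromosome on its right,
                # so they face a centromere to their left; '+' arrays face right.
                faces_nearer = (tel.orientation == "-" and nearer_left) or (
                    tel.orientation == "+" and not nearer_left
                )
                if faces_nearer:
                    pair_cuts.append((tel.end if nearer_left else tel.start, "telomere"))
            if not pair_cuts:
                gaps = _n_gaps(rec.sequence, left.end, right.start)
                if gaps:
                    largest = max(gaps, key=lambda g: g[1] - g[0])
                    pair_cuts.append(((largest[0] + largest[1]) // 2, "gap"))
                else:
                    events.append(SplitEvent(rec.id, -1, "unresolved"))
            cuts.extend(pair_cuts)
        positions = sorted({p for p, _ in cuts if 0 < p < len(rec.sequence)})
        if not positions:
            out.append(rec)
            continue
        for p, reason in sorted(cuts):
            events.append(SplitEvent(rec.id, p, reason))
        bounds = [0] + positions + [len(rec.sequence)]
        for i, (s, e) in enumerate(zip(bounds, bounds[1:]), 1):
            out.append(SequenceRecord(f"{rec.id}.{i}", rec.sequence[s:e]))
    return out, events


def classify_arms(
    scaffolds: list[SequenceRecord],
    regions: list[CentromericRegion],
    telomere_hits: list[RepeatHit],
    end_window: int = DEFAULT_END_WINDOW,
) -> dict[str, str]:
    """Label centromere-bearing scaffolds by terminal-telomere presence.

    A telomere is terminal when its array lies within ``end_window`` of
    either scaffold terminus.
    """
    lengths = {r.id: len(r) for r in scaffolds}
    cen_scaffolds = {r.scaffold for r in regions}
    labels: dict[str, str] = {}
    for sc in sorted(cen_scaffolds):
        terminal = any(
            t.scaffold == sc
            and (t.start < end_window or t.end > lengths.get(sc, 0) - end_window)
            for t in telomere_hits
        )
        labels[sc] = "arm_with_telomere_end" if terminal else "centromeric_no_telomere"
    return labels


# ---------------------------------------------------------------------------
# Assembly statistics


def _n50(lengths: list[int], half: float) -> int | None:
    total = 0
    for length in sorted(lengths, reverse=True):
        total += length
        if total >= half:
            return length
    return None


def assembly_stats(
    scaffolds: list[SequenceRecord],
    fixed_genome_size: int | None = None,
    contig_gap_min: int = DEFAULT_CONTIG_GAP_MIN,
) -> AssemblyStats:
    """Scaffold/contig totals, N50 and (optionally) NG50.

    Contigs are scaffold stretches between N-runs of >= ``contig_gap_min``
    bases. NG50 uses half of ``fixed_genome_size`` instead of half the
    assembly span and may be undefined (None) for incomplete assemblies.
    """
    if fixed_genome_size is not None and fixed_genome_size <= 0:
        raise ValueError("fixed_genome_size must be positive")
    scaffold_lengths = [len(r) for r in scaffolds]
    gap_re = re.compile(rf"[Nn]{{{contig_gap_min},}}")
    contig_lengths: list[int] = []
    for rec in scaffolds:
        contig_lengths.extend(
            len(part) for part in gap_re.split(rec.sequence) if part
        )
    total = sum(scaffold_lengths)
    stats = AssemblyStats(
        total_bp=total,
        n_scaffolds=len(scaffold_lengths),
        n_contigs=len(contig_lengths),
        scaffold_n50=_n50(scaffold_lengths, total / 2) or 0,
        contig_n50=_n50(contig_lengths, sum(contig_lengths) / 2) or 0,
    )
    if fixed_genome_size is not None:
        stats.scaffold_ng50 = _n50(scaffold_lengths, fixed_genome_size / 2)
        stats.contig_ng50 = _n50(contig_lengths, fixed_genome_size / 2)
    return stats
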