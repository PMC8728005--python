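"""Repeat detection, region merging, scaffold splitting, assembly stats."""

import numpy as np
import pytest

from redwoodkit import scaffold_curation as sc
from redwoodkit.core import SequenceRecord, revcomp
from redwoodkit.scaffold_curation import CentromericRegion, RepeatHit

from oracles import transitive_closure_merge

CONS = sc.load_centromere_consensus()


def _rec(seq, name="s"):
    return SequenceRecord(name, seq)


class TestTelomereScan:
    def test_plus_array_at_five_prime(self):
        seq = "CCCTAAA" * 30 + "G" * 500
        (h,) = sc.scan_telomeres(_rec(seq))
        assert (h.start, h.end, h.orientation) == (0, 210, "+")

    def test_reverse_complement_array_is_minus(self):
        seq = "G" * 500 + revcomp("CCCTCAA" * 30)
        (h,) = sc.scan_telomeres(_rec(seq))
        assert h.orientation == "-" and h.end == 710

    def test_short_array_below_threshold_ignored(self):
        assert sc.scan_telomeres(_rec("CCCTAAA" * 2 + "G" * 300)) == []

    def test_mixed_variants_chain_into_one_run(self):
        seq = ("CCCTAAA" + "CCCTCAA") * 10 + "G" * 300
        (h,) = sc.scan_telomeres(_rec(seq))
        assert h.end - h.start == 140 and h.identity == 1.0

    def test_one_corrupted_copy_tolerated(self):
        seq = "CCCTAAA" * 10 + "CCGTAAA" + "CCCTAAA" * 10 + "G" * 300
        (h,) = sc.scan_telomeres(_rec(seq))
        assert (h.start, h.end) == (0, 147)


class TestCentromereScan:
    def test_exact_copy_full_identity(self):
        seq = "G" * 300 + CONS + "G" * 300
        (h,) = sc.scan_centromeres(_rec(seq))
        assert h.identity == 1.0 and h.start == 300 and h.end == 448

    def test_diverged_copy_detected_at_threshold(self):
        rng = np.random.default_rng(5)
        copy = list(CONS)
        for i in rng.choice(len(copy), 14, replace=False):  # ~10% substitutions
            copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
        seq = "G" * 200 + "".join(copy) + "G" * 200
        hits = sc.scan_centromeres(_rec(seq), min_identity=0.8)
        assert len(hits) == 1

    def test_reverse_strand_copy_found(self):
        seq = "G" * 200 + revcomp(CONS) + "G" * 200
        (h,) = sc.scan_centromeres(_rec(seq))
        assert h.orientation == "-"

    def test_wrong_length_consensus_rejected(self):
        with pytest.raises(ValueError, match="148"):
            sc.scan_centromeres(_rec("ACGT" * 100), consensus="ACGT")


def _cen_hits(gaps, width=148, scaffold="s"):
    """Hits laid out with the given inter-hit gaps."""
    hits, pos = [], 0
    for i, gap in enumerate([0, *gaps]):
        pos += gap
        hits.append(RepeatHit(scaffold, pos, pos + width, "centromere", "+", 1.0))
        pos += width
    return hits


class TestMergeRegions:
    def test_gap_below_threshold_merges(self):
        regions = sc.merge_centromeric_hits(_cen_hits([100_000]))
        assert len(regions) == 1 and regions[0].copy_count == 2

    def test_gap_exactly_at_threshold_separates(self):
        regions = sc.merge_centromeric_hits(_cen_hits([250_000]))
        assert len(regions) == 2

    def test_idempotent_and_satisfies_separation(self):
        rng = np.random.default_rng(0)
        hits = _cen_hits(list(rng.integers(1_000, 600_000, 30)))
        regions = sc.merge_centromeric_hits(hits)
        again = sc.merge_centromeric_hits(
            [RepeatHit(r.scaffold, r.start, r.end, "centromere", "+", 1.0) for r in regions]
        )
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in regions]
        for a, b in zip(regions, regions[1:]):
            assert b.start - a.end >= 250_000

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hits = _cen_hits(list(rng.integers(1_000, 500_000, 40)))
        regions = sc.merge_centromeric_hits(hits)
        oracle = transitive_closure_merge([(h.start, h.end) for h in hits], 250_000)
        assert len(regions) == len(oracle)
        assert sorted((r.start, r.end) for r in regions) == sorted(
            (min(s for s, _ in cl), max(e for _, e in cl)) for cl in oracle
        )

    def test_forty_copy_layout_yields_33_regions(self):
        gaps = [300_000] * 39
        for g in (2, 7, 12, 17, 22, 27, 32):  # 1-based gap indices
            gaps[g - 1] = 100_000
        regions = sc.merge_centromeric_hits(_cen_hits(gaps))
        assert len(regions) == 33


class TestSplitScaffolds:
    def _fused_toy(self):
        """Toy replica of the mis-joined-scaffold case: centromeres near
        positions 760 and 1020 (Kbp scaled to bp here), internal telomeres
        at 779 and 980 facing outward."""
        L = 1400
        seq = ["G"] * L
        regions = [
            CentromericRegion("f", 755, 765, 1),
            CentromericRegion("f", 1015, 1025, 1),
        ]
        tel = [
            RepeatHit("f", 775, 783, "telomere", "-", 1.0),  # 3' end of chrom A
            RepeatHit("f", 976, 984, "telomere", "+", 1.0),  # 5' end of chrom B
        ]
        return SequenceRecord("f", "".join(seq)), regions, tel

    def test_double_split_at_both_telomere_positions(self):
        rec, regions, tel = self._fused_toy()
        out, events = sc.split_scaffolds([rec], regions, tel)
        assert [e.reason for e in events] == ["telomere", "telomere"]
        assert sorted(e.position for e in events) == [783, 976]
        assert [r.id for r in out] == ["f.1", "f.2", "f.3"]

    def test_split_conserves_sequence(self, scaffold_sim):
        _, records, _ = scaffold_sim
        tel = [h for r in records for h in sc.scan_telomeres(r)]
        cen = [h for r in records for h in sc.scan_centromeres(r)]
        regions = sc.merge_centromeric_hits(cen, merge_distance=10_000)
        out, _ = sc.split_scaffolds(records, regions, tel)
        for rec in records:
            pieces = [r.sequence for r in out if r.id == rec.id or r.id.startswith(rec.id + ".")]
            assert "".join(pieces) == rec.sequence

    def test_single_centromere_scaffold_unchanged(self):
        rec = SequenceRecord("s", "G" * 1000)
        out, events = sc.split_scaffolds([rec], [CentromericRegion("s", 100, 200, 1)], [])
        assert out == [rec] and events == []

    def test_gap_rule_when_no_internal_telomere(self):
        seq = "G" * 400 + "N" * 20 + "G" * 380
        rec = SequenceRecord("s", seq)
        regions = [CentromericRegion("s", 50, 60, 1), CentromericRegion("s", 700, 710, 1)]
        out, events = sc.split_scaffolds([rec], regions, [])
        assert [e.reason for e in events] == ["gap"]
        assert events[0].position == 410  # midpoint of the N run
        assert len(out) == 2

    def test_unresolved_pair_left_joined(self):
        rec = SequenceRecord("s", "G" * 1000)
        regions = [CentromericRegion("s", 50, 60, 1), CentromericRegion("s", 900, 910, 1)]
        out, events = sc.split_scaffolds([rec], regions, [])
        assert [e.reason for e in events] == ["unresolved"]
        assert out == [rec]


class TestClassifyArms:
    def test_terminal_telomere_labels_arm(self):
        recs = [SequenceRecord("a", "G" * 5000), SequenceRecord("b", "G" * 5000)]
        regions = [CentromericRegion("a", 2000, 2300, 2), CentromericRegion("b", 2000, 2300, 2)]
        tel = [RepeatHit("a", 10, 220, "telomere", "+", 1.0)]
        labels = sc.classify_arms(recs, regions, tel, end_window=1000)
        assert labels == {"a": "arm_with_telomere_end", "b": "centromeric_no_telomere"}

    def test_internal_telomere_is_not_terminal(self):
        recs = [SequenceRecord("a", "G" * 5000)]
        regions = [CentromericRegion("a", 100, 400, 2)]
        tel = [RepeatHit("a", 2000, 2210, "telomere", "+", 1.0)]  # 2x end_window away
        labels = sc.classify_arms(recs, regions, tel, end_window=1000)
        assert labels["a"] == "centromeric_no_telomere"


class TestAssemblyStats:
    def test_n50_of_known_lengths(self):
        recs = [SequenceRecord(str(i), "A" * n) for i, n in enumerate([10, 9, 8, 7, 6])]
        stats = sc.assembly_stats(recs)
        assert stats.scaffold_n50 == 8  # 10+9+8 = 27 >= 20

    def test_ng50_uses_fixed_genome_size(self):
        recs = [SequenceRecord(str(i), "A" * n) for i, n in enumerate([10, 9, 8, 7, 6])]
        stats = sc.assembly_stats(recs, fixed_genome_size=60)
        assert stats.scaffold_ng50 == 7  # cumulative >= 30 reached at 7

    def test_single_sequence(self):
        stats = sc.assembly_stats([SequenceRecord("x", "A" * 123)])
        assert stats.scaffold_n50 == 123 and stats.n_contigs == 1

    def test_contigs_split_at_n_runs(self):
        rec = SequenceRecord("x", "A" * 100 + "N" * 10 + "A" * 50 + "N" * 5 + "A" * 20)
        stats = sc.assembly_stats([rec], contig_gap_min=10)
        assert stats.n_contigs == 2  # the 5-N run is not a gap
        assert stats.contig_n50 == 100

    def test_nonpositive_fixed_size_rejected(self):
        with pytest.raises(ValueError):
            sc.assembly_stats([SequenceRecord("x", "AA")], fixed_genome_size=0)
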