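"""Gene-model filter rules: thresholds, boundaries, reconciliation."""

import itertools

import pytest

from redwoodkit import annotation_filter as af
from redwoodkit.core import AlignmentRecord, EvidenceFlags, GeneModel


def _model(gid="g", exons=((0, 300),), cds=None, cds_seq=None, protein="",
           evidence=None, mask=0.0, mono=None, source="prediction", strand="+",
           scaffold="s"):
    exons = [tuple(e) for e in exons]
    if cds is None:
        cds = list(exons)
    if cds_seq is None:
        n = sum(e - s for s, e in cds)
        cds_seq = "ATG" + "GGA" * max(0, (n - 6) // 3) + "TAA" if n % 3 == 0 else "ATG" * (n // 3)
    return GeneModel(
        id=gid, scaffold=scaffold, strand=strand, exons=exons, cds=cds,
        cds_seq=cds_seq, protein=protein,
        evidence=evidence or EvidenceFlags(has_similarity_hit=True),
        softmask_fraction=mask, source=source,
    )


class TestStructural:
    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(exons=((0, 150), (158, 308)), cds=[(0, 150), (158, 308)]), "intron_lt_9"),
            (dict(exons=((0, 96),)), "cds_lt_100"),
            (dict(exons=((0, 100),)), "cds_not_multiple_of_3"),
            (dict(exons=((0, 300),), cds_seq="GTG" + "GGA" * 98 + "TAA"), "missing_start"),
            (dict(exons=((0, 300),), cds_seq="ATG" + "GGA" * 99), "missing_stop"),
            (dict(exons=((0, 300),), cds_seq="ATG" + "GGA" * 48 + "TAA" + "GGA" * 49 + "TAA"), "internal_stop"),
            (dict(exons=((0, 5), (100, 400)), cds=[(0, 5), (100, 398)]), "exon_lt_9"),
            (dict(cds=[]), "no_cds"),
        ],
    )
    def test_defect_reasons(self, kwargs, reason):
        passing, report = af.structural_filter([_model(**kwargs)])
        assert passing == [] and report.reasons["g"] == reason

    def test_complete_two_exon_gene_retained(self):
        m = _model(exons=((0, 150), (250, 400)), cds=[(0, 150), (250, 400)])
        passing, report = af.structural_filter([m])
        assert passing == [m] and report.n_removed == 0


class TestFunctional:
    @pytest.mark.parametrize(
        "sim,dom,fam,kept",
        [(False, 0, False, False), (False, 0, True, True),
         (True, 0, False, True), (False, 1, False, True), (True, 2, True, True)],
    )
    def test_any_evidence_retains(self, sim, dom, fam, kept):
        ev = EvidenceFlags(has_similarity_hit=sim, domain_count=dom, has_family_assignment=fam)
        passing, _ = af.functional_filter([_model(evidence=ev)])
        assert bool(passing) is kept


class TestRetroelement:
    @pytest.mark.parametrize(
        "flag,mask,kept",
        [(True, 0.70, False), (True, 0.69, True), (False, 0.95, True), (True, 1.0, False)],
    )
    def test_requires_flag_and_mask(self, flag, mask, kept):
        ev = EvidenceFlags(has_similarity_hit=True, retro_domain_flag=flag)
        passing, _ = af.retroelement_filter([_model(evidence=ev, mask=mask)])
        assert bool(passing) is kept


def _prot_pair(identity):
    """A multi-exonic protein and a mono-exonic copy at a given identity."""
    base = "MSTKLVRAGEQIFPWHDNYC" * 10  # 200 aa
    n_mut = round((1 - identity) * len(base))
    # deterministic mutations at evenly spaced positions
    mut = list(base)
    step = len(base) // max(n_mut, 1)
    for k in range(n_mut):
        i = k * step
        mut[i] = "W" if mut[i] != "W" else "Y"
    return base, "".join(mut)


class TestMonoexonic:
    def _pair_models(self, identity):
        multi_p, mono_p = _prot_pair(identity)
        multi = _model("multi", exons=((0, 300), (400, 700)), cds=[(0, 300), (400, 700)], protein=multi_p)
        mono = _model("mono", exons=((1000, 1600),), protein=mono_p)
        return [multi, mono]

    def test_high_identity_copy_removed(self):
        passing, report = af.monoexonic_filter(self._pair_models(0.80))
        assert report.reasons == {"mono": "processed_pseudogene"}
        assert [m.id for m in passing] == ["multi"]

    def test_below_identity_threshold_retained(self):
        passing, _ = af.monoexonic_filter(self._pair_models(0.60))
        assert {m.id for m in passing} == {"multi", "mono"}

    def test_unique_mono_exonic_retained(self):
        multi = _model("multi", exons=((0, 300), (400, 700)), cds=[(0, 300), (400, 700)],
                       protein="MKLVVF" * 40)
        mono = _model("mono", exons=((1000, 1600),), protein="MQQWEHHYCCDNRS" * 20)
        passing, _ = af.monoexonic_filter([multi, mono])
        assert {m.id for m in passing} == {"multi", "mono"}

    def test_no_multiexonic_reference_keeps_all(self):
        mono = _model("mono", exons=((0, 300),), protein="MAAAA" * 30)
        passing, report = af.monoexonic_filter([mono])
        assert passing == [mono] and "warning" in report.extra

    def test_keep_matches_mode_inverts_direction(self):
        passing, report = af.monoexonic_filter(self._pair_models(0.80), keep_matches=True)
        assert {m.id for m in passing} == {"multi", "mono"}


class TestAlignmentEvidence:
    @pytest.mark.parametrize(
        "identity,coverage,kept",
        [(0.96, 0.97, True), (0.94, 0.99, False), (0.99, 0.95, True), (0.99, 0.94, False)],
    )
    def test_thresholds_inclusive(self, identity, coverage, kept):
        rec = AlignmentRecord("t1", "s", 0, 100, "+", identity, coverage)
        assert bool(af.alignment_evidence_filter([rec])) is kept


class TestOverlapResolution:
    def test_identical_span_keeps_transcriptome_model(self):
        pred = _model("p", source="prediction")
        trans = _model("t", source="transcriptome")
        merged, report = af.resolve_overlaps([pred], [trans])
        assert [m.id for m in merged] == ["t"]
        assert report.reasons == {"p": "superseded_by_transcriptome"}

    def test_opposite_strands_both_kept(self):
        merged, _ = af.resolve_overlaps([_model("p", strand="+")], [_model("t", strand="-")])
        assert {m.id for m in merged} == {"p", "t"}

    def test_disjoint_models_both_kept(self):
        merged, _ = af.resolve_overlaps(
            [_model("p")], [_model("t", exons=((5000, 5300),))]
        )
        assert {m.id for m in merged} == {"p", "t"}


class TestPipeline:
    def test_each_stage_reconciles(self, gene_sim):
        _, models, _, _, _ = gene_sim
        _, reports = af.run_filter_pipeline(models)
        for r in reports:
            assert r.n_removed + r.n_retained == r.n_input

    def test_stage_order_is_fixed(self, gene_sim):
        _, models, _, _, _ = gene_sim
        _, reports = af.run_filter_pipeline(models)
        assert [r.rule for r in reports] == [
            "structural", "functional", "retroelement", "monoexonic"
        ]

    def test_disjoint_reason_classes_commute(self):
        """Filters with disjoint targets give the same survivors in any order."""
        models = [
            _model("ok"),
            _model("noev", evidence=EvidenceFlags()),
            _model("retro", evidence=EvidenceFlags(has_similarity_hit=True, retro_domain_flag=True), mask=0.9),
        ]
        stages = {
            "functional": lambda ms: af.functional_filter(ms)[0],
            "retro": lambda ms: af.retroelement_filter(ms)[0],
        }
        outcomes = set()
        for order in itertools.permutations(stages.values()):
            ms = list(models)
            for stage in order:
                ms = stage(ms)
            outcomes.add(tuple(sorted(m.id for m in ms)))
        assert outcomes == {("ok",)}
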