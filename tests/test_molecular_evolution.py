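"""Divergence estimators and the topology classifier."""

import math

import dendropy
import numpy as np
import pytest

from redwoodkit import molecular_evolution as me
from redwoodkit import synthetic_data as sd


def _tree(nwk):
    return dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)


class TestKimura2P:
    def test_identical_sequences(self):
        d = me.kimura2p("ACGTACGT", "ACGTACGT")
        assert d.K == 0 and d.P == d.Q == 0 and d.sites_used == 8

    def test_closed_form_value(self):
        # 100 sites, 10 transitions (A->G), 5 transversions (C->A):
        # K = -1/2 ln((1 - 0.25) sqrt(1 - 0.1)) = 0.170181
        a = "A" * 10 + "C" * 5 + "T" * 85
        b = "G" * 10 + "A" * 5 + "T" * 85
        d = me.kimura2p(a, b)
        assert (d.P, d.Q) == (0.10, 0.05)
        expected = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(1 - 2 * 0.05))
        assert d.K == pytest.approx(expected, abs=1e-12)
        assert d.K == pytest.approx(0.170181, abs=1e-6)

    def test_saturation_flagged(self):
        # 20 sites with 10 transitions and 8 transversions: 1-2P-Q < 0
        a = "A" * 10 + "C" * 8 + "G" * 2
        b = "G" * 10 + "A" * 8 + "G" * 2
        d = me.kimura2p(a, b)
        assert d.saturated and d.K is None

    def test_gaps_and_ambiguity_deleted_pairwise(self):
        d = me.kimura2p("ACG-TN", "ACGTTA")
        assert d.sites_used == 4

    def test_jukes_cantor_limit(self):
        """With transitions = half of transversions (all substitution types
        equally likely), K2P collapses to the Jukes-Cantor formula."""
        for p in (0.01, 0.03, 0.06, 0.09):
            n = 30000
            nP, nQ = round(p * n / 3), round(2 * p * n / 3)
            a = "A" * nP + "C" * nQ + "T" * (n - nP - nQ)
            b = "G" * nP + "A" * nQ + "T" * (n - nP - nQ)
            d = me.kimura2p(a, b)
            p_obs = d.P + d.Q
            jc = -0.75 * math.log(1 - 4 * p_obs / 3)
            assert d.K == pytest.approx(jc, abs=1e-6)

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            me.kimura2p("ACGT", "ACG")


class TestPairwiseDnDs:
    def test_identical_sequences_have_na_omega(self):
        cds = "ATGAAACCCGGGTTTCTT"
        r = me.pairwise_dnds(cds, cds)
        assert r.dN == 0 and r.dS == 0 and r.omega is None

    def test_single_synonymous_change(self):
        a = "ATG" + "CTT" * 99
        b = "ATG" + "CTT" * 98 + "CTC"  # Leu -> Leu at the last codon
        r = me.pairwise_dnds(a, b)
        assert r.dN == 0 and r.dS > 0

    def test_single_nonsynonymous_change(self):
        a = "ATG" + "CTT" * 99
        b = "ATG" + "CTT" * 98 + "CGT"  # Leu -> Arg
        r = me.pairwise_dnds(a, b)
        assert r.dS == 0 and r.dN > 0 and r.omega is None

    def test_sites_sum_to_three_per_codon(self):
        a = "ATGAAACCCGGGTTTCTT"
        b = "ATGAAGCCCGGATTTCTT"
        r = me.pairwise_dnds(a, b)
        assert r.N + r.S == pytest.approx(3 * r.codons_used)

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(1)
        a = sd._random_cds(rng, 200)
        b = sd._mutate_protein_level(rng, a, 0.9)
        r1, r2 = me.pairwise_dnds(a, b), me.pairwise_dnds(b, a)
        assert r1.dN == pytest.approx(r2.dN) and r1.dS == pytest.approx(r2.dS)

    def test_neutral_substitutions_give_omega_near_one(self):
        """Substitutions placed uniformly at random, blind to codon
        structure, must yield dN/dS close to 1."""
        rng = np.random.default_rng(11)
        a = sd._random_cds(rng, 10_000)
        b = list(a)
        for i in rng.choice(len(b), round(0.08 * len(b)), replace=False):
            b[i] = "ACGT"[rng.integers(0, 4)]
        r = me.pairwise_dnds(a, "".join(b))
        assert r.omega == pytest.approx(1.0, abs=0.1)

    def test_agreement_with_independent_ng86_implementation(self):
        """Cross-check against Biopython's NG86 counting on a stop-free
        pair; conventions for nonsense mutations differ slightly, so the
        comparison is at the few-percent level, not exact."""
        from Bio.Align import Alignment, analysis

        rng = np.random.default_rng(7)
        stops = set(sd.STOP_CODONS)

        def codon():
            while True:
                c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
                if c not in stops:
                    return c

        cods = [codon() for _ in range(800)]
        a = "".join(cods)
        b_cods = list(cods)
        for i in rng.choice(len(cods), 60, replace=False):
            while True:
                c = list(b_cods[i])
                c[rng.integers(0, 3)] = "ACGT"[rng.integers(0, 4)]
                c = "".join(c)
                if c not in stops:
                    break
            b_cods[i] = c
        b = "".join(b_cods)
        aln = Alignment([a, b], coordinates=np.array([[0, len(a)], [0, len(b)]]))
        dn_ref, ds_ref = analysis.calculate_dn_ds(aln, method="NG86")
        r = me.pairwise_dnds(a, b)
        assert r.dN == pytest.approx(dn_ref, rel=0.10)
        assert r.dS == pytest.approx(ds_ref, rel=0.10)

    def test_frameshifted_length_rejected(self):
        with pytest.raises(ValueError):
            me.pairwise_dnds("ATGA", "ATGA")


class TestClassifyTopology:
    def test_monophyletic_with_clear_sister(self):
        call = me.classify_topology(_tree("(((CR_1,CR_2),GS_1),(MG_1,OUT_1));"), "CR")
        assert call.focal_monophyletic and call.sister == "GS"
        assert call.n_focal_copies == 2

    def test_interleaved_copies_not_monophyletic(self):
        call = me.classify_topology(_tree("(((CR_1,GS_1),(CR_2,MG_1)),OUT_1);"), "CR")
        assert not call.focal_monophyletic and call.sister == ""

    def test_both_candidates_in_sibling_is_unclear(self):
        call = me.classify_topology(_tree("(((CR_1,CR_2),(GS_1,MG_1)),OUT_1);"), "CR")
        assert call.focal_monophyletic and call.sister == "unclear"

    def test_three_copies(self):
        call = me.classify_topology(
            _tree("((((CR_1,CR_2),CR_3),MG_1),(GS_1,OUT_1));"), "CR"
        )
        assert call.focal_monophyletic and call.sister == "MG"
        assert call.n_focal_copies == 3

    def test_support_threshold_downgrades_call(self):
        nwk = "(((CR_1,CR_2)55,GS_1),(MG_1,OUT_1));"
        call = me.classify_topology(_tree(nwk), "CR", support_threshold=70)
        assert call.focal_monophyletic and call.sister == "unclear"
        call2 = me.classify_topology(_tree(nwk), "CR", support_threshold=50)
        assert call2.sister == "GS" and call2.support_at_focal_clade == 55

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError, match="outgroup"):
            me.classify_topology(_tree("((CR_1,CR_2),GS_1);"), "CR")

    def test_single_copy_rejected(self):
        with pytest.raises(ValueError, match="two focal"):
            me.classify_topology(_tree("((CR_1,GS_1),OUT_1);"), "CR")


class TestTally:
    def test_counts_by_class(self):
        calls = [
            me.TopologyCall("1", True, 2, "GS"),
            me.TopologyCall("2", True, 3, "GS"),
            me.TopologyCall("3", True, 2, "unclear"),
            me.TopologyCall("4", False, 3, ""),
        ]
        t = me.tally_topologies(calls)
        assert t["monophyletic_sister_GS"] == 2
        assert t["monophyletic_sister_MG"] == 0
        assert t["monophyletic_unclear"] == 1
        assert t["non_monophyletic"] == 1
        assert t["by_copy_number"][2]["monophyletic_sister_GS"] == 1

    def test_empty_input(self):
        t = me.tally_topologies([])
        assert t["n_trees"] == 0 and t["non_monophyletic"] == 0

    def test_noise_free_auto_scenario_is_all_one_class(self):
        nwks = sd.gen_gene_trees(sd.GeneTreeConfig(n_trees=50), 4, scenario="auto")
        calls = [me.classify_topology(_tree(n), "CR") for n in nwks]
        t = me.tally_topologies(calls)
        assert t["monophyletic_sister_GS"] == 50

    def test_classification_degrades_monotonically_with_nni_noise(self):
        correct = []
        for moves in (0, 2, 6):
            nwks = sd.gen_gene_trees(
                sd.GeneTreeConfig(n_trees=60, nni_moves=moves), 8, scenario="auto"
            )
            calls = [me.classify_topology(_tree(n), "CR") for n in nwks]
            correct.append(
                sum(1 for c in calls if c.focal_monophyletic and c.sister == "GS")
            )
        assert correct[0] == 60 and correct[0] >= correct[1] >= correct[2]
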