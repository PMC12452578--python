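import pytest

from mabseq.chain_qc import annotate_orf, compare_to_strain, flag_aberrant
from mabseq.errors import ValidationError
from mabseq.io import ReferenceRecord


def _ref(seq, id="ref", category="constant_region", label="X"):
    return ReferenceRecord(id, seq, category, subclass_or_strain=label)


class TestAnnotateOrf:
    def test_forced_early_stop_is_premature(self):
        downstream = "GCT" * 40
        report = annotate_orf("ATGGCTTAA" + downstream)
        assert report.premature_stop
        assert report.stop_position_aa == 3
        assert report.protein == "MA"
        assert report.leader_detected

    def test_productive_kappa_fixture_has_no_premature_stop(self, kappa_consensus):
        report = annotate_orf(kappa_consensus)
        assert not report.premature_stop
        assert report.leader_detected
        assert report.frame_offset == report.start_nt % 3

    def test_aberrant_kappa_fixture_is_flagged(self, aberrant_consensus):
        """The 1-nt V-J junction deletion reads into a stop shortly after."""
        report = annotate_orf(aberrant_consensus)
        assert report.premature_stop
        assert report.stop_position_aa is not None

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            annotate_orf("ATGGCT")

    def test_translation_matches_bruteforce_codon_table(self, kappa_consensus):
        from Bio.Seq import Seq

        report = annotate_orf(kappa_consensus)
        coding = kappa_consensus[report.start_nt:]
        coding = coding[: len(coding) - len(coding) % 3]
        expected = str(Seq(coding).translate()).split("*")[0]
        assert report.protein == expected


class TestFlagAberrant:
    def test_self_match_against_reference(self, world):
        ref = world.references["aberrant_kappa"][0]
        call = flag_aberrant(ref.sequence, world.references["aberrant_kappa"])
        assert call.flagged and call.reason == "reference_match"
        assert call.best_identity == pytest.approx(1.0)

    def test_productive_chain_not_flagged(self, world, kappa_consensus):
        call = flag_aberrant(kappa_consensus, world.references["aberrant_kappa"])
        assert not call.flagged
        assert call.best_identity < 0.95

    def test_half_of_kappa_clones_flagged(self, world, kappa_reads, kappa_clusters):
        """Exactly the aberrant cluster is flagged, i.e. 50% of the reads."""
        _, labels = kappa_reads
        flagged_reads = []
        for cluster in kappa_clusters:
            call = flag_aberrant(cluster.consensus, world.references["aberrant_kappa"])
            if call.flagged:
                flagged_reads.extend(cluster.member_ids)
        assert sorted(labels[r] for r in flagged_reads) == ["aberrant"] * 4

    def test_monotone_in_min_identity(self, world, kappa_consensus, aberrant_consensus):
        for consensus in (kappa_consensus, aberrant_consensus):
            previous = None
            for threshold in (0.80, 0.90, 0.95, 0.99):
                call = flag_aberrant(consensus, world.references["aberrant_kappa"],
                                     min_identity=threshold)
                by_identity = call.flagged and call.reason == "reference_match"
                if previous is not None:
                    assert not (by_identity and not previous)
                previous = by_identity


class TestCompareToStrain:
    def test_sample_vs_itself_has_no_differences(self):
        seq = "ATGGCTGCTGCTAAAGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCT"
        (comp,) = compare_to_strain(seq, [_ref(seq)])
        assert comp.nt_differences == [] and comp.aa_differences == []

    def test_nod_ranked_first_with_zero_differences(self, world):
        truth = world.truth
        constant = world.heavy_mrna[truth.heavy_regions["CH1"][0]:truth.heavy_regions["stop"][0]]
        comps = compare_to_strain(constant, world.references["constant_heavy_strain"])
        assert comps[0].strain_b_id == "IGHG2c-NOD"
        assert comps[0].nt_differences == []

    def test_dinucleotide_swap_reported_as_valine_glycine_exchange(self, world):
        """TG<->GT swap in CH3: one aa difference at mature position 435."""
        truth = world.truth
        constant = world.heavy_mrna[truth.heavy_regions["CH1"][0]:truth.heavy_regions["stop"][0]]
        comps = compare_to_strain(constant, world.references["constant_heavy_strain"],
                                  aa_offset=truth.vh_aa_len)
        c57 = next(c for c in comps if "C57" in c.strain_b_id)
        assert len(c57.nt_differences) == 2
        assert c57.aa_differences == [(truth.strain_swap_position_aa, "G", "V")]
        assert truth.strain_swap_position_aa == 435

    def test_symmetry_under_swapping_sample_and_reference(self, world):
        refs = world.references["constant_heavy_strain"]
        nod, c57 = (r for r in sorted(refs, key=lambda r: r.id, reverse=True))
        (forward,) = compare_to_strain(nod.sequence, [c57])
        (backward,) = compare_to_strain(c57.sequence, [_ref(nod.sequence)])
        assert [(p, b, a) for p, a, b in forward.nt_differences] == backward.nt_differences
        assert [(p, b, a) for p, a, b in forward.aa_differences] == backward.aa_differences

    def test_short_reference_rejected(self):
        with pytest.raises(ValidationError, match="50"):
            compare_to_strain("A" * 60, [_ref("ACGT" * 10)])
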