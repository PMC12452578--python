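import numpy as np
import pytest

from mabseq.align import revcomp
from mabseq.errors import ValidationError
from mabseq.fixtures import HEAVY_CDR3_NT, KAPPA_CDR3_NT
from mabseq.io import ReferenceRecord
from mabseq.vdj import annotate_chain, assign_germline, find_cdr3


class TestFindCdr3:
    def test_heavy_junction_recovered_exactly(self, world, heavy_consensus):
        nt, aa, span = find_cdr3(heavy_consensus, "heavy",
                                 world.references["germline_V_heavy"],
                                 world.references["germline_J_heavy"])
        assert nt == HEAVY_CDR3_NT == "GTCAGATACGGTGGTGGAGGGTTTGCTTAC"
        assert aa == "VRYGGGGFAY"
        assert heavy_consensus[span[0]:span[1]] == nt

    def test_kappa_junction_recovered_exactly(self, world, kappa_consensus):
        nt, aa, _ = find_cdr3(kappa_consensus, "kappa",
                              world.references["germline_V_kappa"],
                              world.references["germline_J_kappa"])
        assert nt == KAPPA_CDR3_NT == "CAGCAGTATCATAGTTACCCACGGACG"
        assert aa == "QQYHSYPRT"

    @pytest.mark.parametrize("seed", range(8))
    def test_planted_random_junction_is_recovered(self, world, seed):
        """Embedding any in-frame CDR3 between the V/J anchors is invertible."""
        rng = np.random.default_rng(seed)
        n_codons = int(rng.integers(3, 21))
        pool = "ADEFGHILMNQSTVY"
        from mabseq.fixtures import _revtrans
        cdr3 = _revtrans(rng, "".join(pool[i] for i in rng.integers(0, len(pool), n_codons)))
        v = world.references["germline_V_heavy"][0].sequence
        j = world.references["germline_J_heavy"][0].sequence
        template = "ATG" + v + cdr3 + j + world.ch1_by_subclass["IgG2c"][:90]
        nt, _, _ = find_cdr3(template, "heavy",
                             world.references["germline_V_heavy"],
                             world.references["germline_J_heavy"])
        assert nt == cdr3


class TestAssignGermline:
    def test_self_match_scores_100(self):
        ref = ReferenceRecord("V1", "ACGT" * 60, "germline_V")
        result = assign_germline("ACGT" * 60, [ref])
        assert result.calls == ["V1"]
        assert result.top_identity_pct == pytest.approx(100.0)

    def test_two_substitutions_over_200_nt_score_99(self):
        seq = ("ACGT" * 50)
        mutated = "T" + seq[1:100] + "G" + seq[101:]
        ref = ReferenceRecord("V1", seq, "germline_V")
        result = assign_germline(mutated, [ref])
        assert result.top_identity_pct == pytest.approx(99.0)

    def test_cobest_references_are_tied(self, world, heavy_consensus):
        """Identical germline alleles are reported together (Table-style ties)."""
        result = assign_germline(heavy_consensus, world.references["germline_V_heavy"])
        assert result.calls == ["IGHV-2*01", "IGHV2-6-8*01"]
        d = assign_germline(heavy_consensus, world.references["germline_D"])
        assert d.calls == ["IGHD-1*01", "IGHD-1*02"]

    def test_invariant_to_reference_order_and_orientation(self, world, heavy_consensus):
        refs = world.references["germline_V_heavy"]
        a = assign_germline(heavy_consensus, refs)
        b = assign_germline(heavy_consensus, list(reversed(refs)))
        c = assign_germline(revcomp(heavy_consensus), refs)
        assert a.calls == b.calls == c.calls
        assert a.top_identity_pct == pytest.approx(c.top_identity_pct)

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValidationError):
            assign_germline("ACGT" * 30, [])


class TestAnnotateChain:
    def test_heavy_annotation_summary(self, world, heavy_consensus):
        ann = annotate_chain(heavy_consensus, "heavy",
                             world.references["germline_V_heavy"],
                             world.references["germline_J_heavy"],
                             world.references["germline_D"])
        assert ann.productive
        assert ann.d_call == "IGHD-1*01,IGHD-1*02"
        assert ann.j_call == "IGHJ3*01"
        # four planted somatic mutations over the 288-nt germline V
        assert ann.total_identity_pct == pytest.approx(100 * (288 - 4) / 288, abs=0.01)

    def test_light_chain_has_no_d_call(self, world, kappa_consensus):
        ann = annotate_chain(kappa_consensus, "kappa",
                             world.references["germline_V_kappa"],
                             world.references["germline_J_kappa"])
        assert ann.d_call == ""
        assert ann.v_call == "IGKV4-61*01"

    def test_reverse_complement_input_is_reoriented(self, world, heavy_consensus):
        ann = annotate_chain(revcomp(heavy_consensus), "heavy",
                             world.references["germline_V_heavy"],
                             world.references["germline_J_heavy"])
        assert ann.cdr3_nt == HEAVY_CDR3_NT
        assert ann.orientation == "-"
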