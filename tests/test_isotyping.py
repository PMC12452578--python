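import numpy as np
import pytest

from mabseq.align import revcomp
from mabseq.errors import ValidationError
from mabseq.fixtures import SUBCLASSES, _heavy_amplicon_for
from mabseq.io import PrimerRecord, ReferenceRecord
from mabseq.isotyping import call_isotype, derive_motifs, scan_primer_sites


@pytest.fixture(scope="module")
def motifs(world):
    return derive_motifs(world.references["CH1_exon"])


def _ch1(id, seq, subclass):
    return ReferenceRecord(id, seq, "CH1_exon", subclass_or_strain=subclass)


class TestDeriveMotifs:
    def test_single_difference_gives_each_side_a_motif(self):
        rng = np.random.default_rng(7)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        other = base[:10] + ("C" if base[10] != "C" else "G") + base[11:]
        result = derive_motifs([_ch1("a", base, "IgG1"), _ch1("b", other, "IgG2a")])
        assert result.motifs["IgG1"] and result.motifs["IgG2a"]
        for _subclass, motif, off in result.all_motifs():
            assert off <= 10 < off + len(motif)  # unique windows cover the difference

    def test_every_bundled_subclass_receives_a_motif(self, motifs):
        assert set(motifs.motifs) == set(SUBCLASSES)
        assert all(len(v) >= 1 for v in motifs.motifs.values())

    def test_motif_soundness_each_hits_exactly_one_subclass(self, world, motifs):
        """Exhaustive scan: every motif occurs in its own CH1 and no other."""
        for subclass, motif, _ in motifs.all_motifs():
            hits = {s for s, seq in world.ch1_by_subclass.items()
                    if motif in seq or motif in revcomp(seq)}
            assert hits == {subclass}

    def test_duplicate_reference_sequences_rejected(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        with pytest.raises(ValidationError, match="no unique window"):
            derive_motifs([_ch1("a", seq, "IgG1"), _ch1("b", seq, "IgG2a")])


class TestCallIsotype:
    @pytest.mark.parametrize("subclass", SUBCLASSES)
    def test_planted_subclass_recovered(self, world, motifs, subclass):
        amplicon = _heavy_amplicon_for(world, subclass)
        call = call_isotype(amplicon, motifs, world.references["constant_light"])
        assert call.subclass == subclass

    def test_consensus_without_ch1_stub_is_ambiguous(self, world, motifs):
        variable_only = world.heavy_mrna[:world.truth.heavy_regions["CH1"][0]]
        call = call_isotype(variable_only, motifs, [])
        assert call.subclass == "ambiguous"
        assert call.evidence == []

    def test_kappa_consensus_calls_kappa_light_chain(self, world, motifs, kappa_consensus):
        call = call_isotype(kappa_consensus, motifs, world.references["constant_light"])
        assert call.light_chain == "kappa"
        assert call.subclass == "ambiguous"

    def test_heavy_consensus_has_no_light_chain(self, world, motifs, heavy_consensus):
        call = call_isotype(heavy_consensus, motifs, world.references["constant_light"])
        assert call.light_chain == "none"
        assert call.subclass == "IgG2c"


class TestScanPrimerSites:
    def test_rt_primer_matches_four_subclasses_exactly(self, world):
        """The heavy RT primer shows 0 mismatches except 5 against IgG3."""
        rt = next(p for p in world.primers if p.name == "mIGHG-RT")
        reports = {r.reference_id: r for r in
                   scan_primer_sites(rt, world.references["CH1_exon"])}
        for subclass in ("IgG1", "IgG2a", "IgG2b", "IgG2c"):
            assert reports[f"IGHG-{subclass}-CH1"].mismatches == 0
        igg3 = reports["IGHG-IgG3-CH1"]
        assert igg3.mismatches == 5
        assert len(igg3.mismatch_positions) == 5

    def test_pcr_primer_mismatch_pattern(self, world):
        """PCR primer: one mismatch vs IgG2b, four vs IgG3, none elsewhere."""
        pcr = next(p for p in world.primers if p.name == "mIGHG-PCR")
        counts = {r.reference_id: r.mismatches for r in
                  scan_primer_sites(pcr, world.references["CH1_exon"])}
        assert counts == {"IGHG-IgG1-CH1": 0, "IGHG-IgG2a-CH1": 0,
                          "IGHG-IgG2b-CH1": 1, "IGHG-IgG2c-CH1": 0,
                          "IGHG-IgG3-CH1": 4}

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_bruteforce_minimum_hamming_search(self, seed):
        rng = np.random.default_rng(seed)
        ref_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        primer_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 18))
        primer = PrimerRecord("p", primer_seq, "vdj_specific")
        ref = ReferenceRecord("r", ref_seq, "germline_V")
        (report,) = scan_primer_sites(primer, [ref])
        best = min(
            sum(a != b for a, b in zip(probe, ref_seq[off:off + 18]))
            for probe in (primer_seq, revcomp(primer_seq))
            for off in range(len(ref_seq) - 18 + 1)
        )
        assert report.mismatches == best

    def test_primer_longer_than_reference_rejected(self):
        with pytest.raises(ValidationError):
            scan_primer_sites(PrimerRecord("p", "A" * 30, "RT"),
                              [ReferenceRecord("r", "ACGT" * 5, "CH1_exon",
                                               subclass_or_strain="IgG1")])
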