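import numpy as np
import pytest

from mabseq.errors import ValidationError
from mabseq.fingerprint import (CdrSpan, PeptideMatch, cdr_spans, cleavage_sites,
                                digest, match_peaks, peptide_mass)
from mabseq.io import PeakList

GLY_MH = 57.02146 + 18.010565 + 1.007276


def brute_force_digest(protein, mode, max_missed, length_range=(4, 40)):
    """Independent enumeration: every substring whose boundaries are cleavage
    boundaries (or termini) and whose internal cut count is within budget."""
    if mode == "trypsin":
        internal = {i for i in range(1, len(protein))
                    if protein[i - 1] in "KR" and protein[i] != "P"}
    else:
        internal = {i for i in range(1, len(protein))
                    if protein[i - 1] == "D" or protein[i] == "D"}
    boundaries = internal | {0, len(protein)}
    out = set()
    for s in range(len(protein)):
        for e in range(s + 1, len(protein) + 1):
            if s not in boundaries or e not in boundaries:
                continue
            inside = sum(1 for c in internal if s < c < e)
            if inside <= max_missed and length_range[0] <= e - s <= length_range[1]:
                out.add((s + 1, e, protein[s:e]))
    return out


class TestDigest:
    def test_kp_bond_not_cleaved(self):
        peptides = digest("AAKPGGRAA", "trypsin", max_missed=0)
        assert [p.sequence for p in peptides] == ["AAKPGGR"]

    def test_acid_cleaves_both_sides_of_aspartate(self):
        sites = cleavage_sites("GGDGG", "acid")
        assert sites == [2, 3]
        fragments = {p.sequence for p in digest("GGDGGGGDGG", "acid", max_missed=0)}
        assert fragments == {"GGGG"}  # only the middle piece passes the length filter

    def test_nonstandard_residue_named(self):
        with pytest.raises(ValidationError, match="position 4"):
            digest("AAKBB", "trypsin")

    def test_missed_site_budget_controls_fragments(self):
        protein = "AAAKGGGKCCCC"
        none = {p.sequence for p in digest(protein, "trypsin", max_missed=0)}
        one = {p.sequence for p in digest(protein, "trypsin", max_missed=1)}
        assert none <= one
        assert "AAAKGGGK" in one and "AAAKGGGK" not in none

    @pytest.mark.parametrize("mode", ["trypsin", "acid"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_enumeration(self, mode, seed):
        rng = np.random.default_rng(seed)
        protein = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 60))
        for max_missed in (0, 2, 3):
            got = {(p.start, p.end, p.sequence)
                   for p in digest(protein, mode, max_missed=max_missed)}
            assert got == brute_force_digest(protein, mode, max_missed)


class TestPeptideMass:
    def test_glycine_reference_value(self):
        assert peptide_mass("G") == pytest.approx(GLY_MH, abs=1e-4)

    def test_residue_additivity(self):
        assert peptide_mass("AG") - peptide_mass("G") == pytest.approx(71.03711, abs=1e-4)

    def test_concatenation_rule(self):
        a, b = "PEPTIDE", "KRAFTWERK"
        assert peptide_mass(a + b) == pytest.approx(
            peptide_mass(a) + peptide_mass(b) - 18.010565 - 1.007276, abs=1e-6)

    def test_carbamidomethyl_adds_per_cysteine(self):
        delta = peptide_mass("ACCA", cys_fixed_mod="carbamidomethyl") - peptide_mass("ACCA")
        assert delta == pytest.approx(2 * 57.021464, abs=1e-6)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            peptide_mass("")


class TestMatchPeaks:
    def test_zero_jitter_matches_everything_at_zero_error(self):
        theory = digest("AAAKGGGKCCCCKDDDDK", "trypsin")
        peaks = [(p.mh_mono, 10.0) for p in sorted(theory, key=lambda p: p.mh_mono)]
        merged = sorted(dict(peaks).items())
        result = match_peaks(merged, theory, tol_ppm=5.0)
        assert len(result.matches) == len(merged)
        assert all(m.error_ppm == pytest.approx(0.0) for m in result.matches)

    def test_empty_peak_list_gives_zero_coverage(self):
        theory = digest("AAAKGGGK", "trypsin")
        spans = [CdrSpan("H-CDR1", "heavy", 1, 3)]
        result = match_peaks([], theory, tol_ppm=100, cdr_spans=spans)
        assert result.coverage_fraction == 0.0
        assert result.cdr_assignments["H-CDR1"][0] is False

    def test_coverage_monotone_in_tolerance(self):
        rng = np.random.default_rng(0)
        theory = digest("ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY", "acid")
        peaks = sorted((p.mh_mono * (1 + rng.normal(0, 40) * 1e-6), 5.0) for p in theory)
        coverages = [match_peaks(peaks, theory, tol).coverage_fraction
                     for tol in (10, 50, 100, 200)]
        assert coverages == sorted(coverages)

    def test_five_of_six_cdrs_assigned_on_benchmark_spectra(self, world):
        """Spectra built to omit one CDR's peptides assign exactly the other five."""
        from mabseq.fixtures import make_cdr_benchmark_peaklists

        peaklists, _ = make_cdr_benchmark_peaklists(world, exclude_label="H-CDR2")
        theory = []
        spans = []
        for chain, protein, cdrs in (
            ("heavy", world.truth.heavy_mature_protein, world.truth.heavy_cdr_spans_aa),
            ("light", world.truth.kappa_mature_protein, world.truth.kappa_cdr_spans_aa),
        ):
            for mode in ("trypsin", "acid"):
                theory.extend(digest(protein, mode, chain=chain))
            prefix = "H" if chain == "heavy" else "L"
            spans.extend(CdrSpan(f"{prefix}-{label}", chain, s, e)
                         for label, (s, e) in cdrs.items())
        assigned = {}
        for mode, peaks in peaklists.items():
            subset = [t for t in theory if t.cleavage_mode == mode]
            result = match_peaks(peaks, subset, tol_ppm=5.0, cdr_spans=spans)
            for label, (ok, _) in result.cdr_assignments.items():
                assigned[label] = assigned.get(label, False) or ok
        assert sum(assigned.values()) == 5
        assert not assigned["H-CDR2"]


class TestCdrSpans:
    def test_cdr3_located_from_junction_peptide(self):
        protein = "M" * 20 + "QQYHSYPRT" + "F" * 20
        spans = cdr_spans("light", protein, "QQYHSYPRT")
        (span,) = spans
        assert (span.start, span.end) == (21, 29)
        assert span.end - span.start + 1 == 9

    def test_reversed_span_rejected(self):
        with pytest.raises(ValidationError, match="end < start"):
            cdr_spans("light", "A" * 50 + "QQY" + "A" * 10, "QQY", cdr1=(9, 3))

    def test_adjacent_spans_accepted_but_overlap_rejected(self):
        protein = "A" * 50 + "WWW" + "A" * 10
        spans = cdr_spans("heavy", protein, "WWW", cdr1=(1, 5), cdr2=(6, 10))
        assert [s.label for s in spans] == ["H-CDR1", "H-CDR2", "H-CDR3"]
        with pytest.raises(ValidationError, match="overlap"):
            cdr_spans("heavy", protein, "WWW", cdr1=(1, 6), cdr2=(6, 10))
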