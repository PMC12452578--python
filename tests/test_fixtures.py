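import numpy as np
import pytest

from mabseq.consensus import cluster_reads
from mabseq.errors import ValidationError
from mabseq.fixtures import (FixtureConfig, build_world, make_antibody_template,
                             make_clone_reads, make_constant_reads,
                             simulate_spectrum)
from mabseq.fingerprint import digest


class TestDeterminism:
    def test_same_seed_gives_identical_world(self):
        a = build_world(FixtureConfig(seed=11))
        b = build_world(FixtureConfig(seed=11))
        assert a.heavy_mrna == b.heavy_mrna
        assert a.kappa_mrna == b.kappa_mrna
        assert [r.sequence for recs in a.references.values() for r in recs] == \
               [r.sequence for recs in b.references.values() for r in recs]

    def test_different_seeds_differ(self):
        a = build_world(FixtureConfig(seed=11))
        b = build_world(FixtureConfig(seed=12))
        assert a.heavy_mrna != b.heavy_mrna


class TestTemplates:
    def test_architecture_and_truth_agree(self, world):
        truth = world.truth
        assert len(world.heavy_mrna) == truth.heavy_regions["polyA"][1]
        assert world.heavy_mrna.endswith("A" * 30)
        lo, hi = truth.heavy_regions["CDR3"]
        assert world.heavy_mrna[lo:hi] == truth.heavy_cdr3_nt
        assert "*" not in truth.heavy_mature_protein
        assert "*" not in truth.kappa_mature_protein
        assert len(truth.heavy_mature_protein) == 446
        assert len(truth.kappa_mature_protein) == 214

    def test_expected_amplicon_lengths(self, world):
        assert 1250 <= world.truth.expected_heavy_product_nt <= 1350
        assert 550 <= world.truth.expected_kappa_product_nt <= 650

    def test_nod_strain_carries_the_swap(self):
        heavy, _, truth = make_antibody_template(FixtureConfig(seed=5, strain="NOD"))
        pos = truth.heavy_regions["V"][0] + 3 * (truth.strain_swap_position_aa - 1)
        assert heavy[pos:pos + 3] == "GGT"  # glycine; C57BL/6J reference has GTG
        heavy_c57, _, _ = make_antibody_template(FixtureConfig(seed=5, strain="C57BL/6J"))
        assert heavy_c57[pos:pos + 3] == "GTG"

    def test_unknown_subclass_rejected(self):
        with pytest.raises(ValidationError):
            FixtureConfig(subclass="IgG4")


class TestCloneReads:
    def test_zero_error_reads_equal_template_substring(self):
        world = build_world(FixtureConfig(seed=2, read_error_rate=0.0,
                                          aberrant_fraction=0.0))
        reads, labels = make_clone_reads(world, "kappa")
        amplicon = world.kappa_mrna[slice(*world.truth.kappa_amplicon)]
        assert all(r.sequence == amplicon for r in reads)
        assert set(labels.values()) == {"productive"}

    def test_aberrant_fraction_is_exact(self, kappa_reads):
        _, labels = kappa_reads
        counts = sorted(labels.values())
        assert counts.count("aberrant") == 4 and counts.count("productive") == 4

    def test_non_integral_aberrant_count_rejected(self, world):
        bad = FixtureConfig(seed=1, n_reads_per_chain=8, aberrant_fraction=0.3)
        with pytest.raises(ValidationError, match="integral"):
            make_clone_reads(world, "kappa", bad)

    def test_constant_reads_cover_cdr3_to_polya(self, world):
        reads = make_constant_reads(world, "heavy", FixtureConfig(seed=1, read_error_rate=0))
        lo = world.truth.heavy_regions["CDR3"][0]
        hi = world.truth.heavy_regions["polyA"][0]
        assert reads[0].sequence == world.heavy_mrna[lo:hi]


class TestSimulateSpectrum:
    def test_identity_channel_reproduces_theoretical_masses(self, world):
        config = FixtureConfig(seed=4, peak_dropout=0.0, mz_jitter_ppm=0.0,
                               n_noise_peaks=0)
        protein = world.truth.kappa_mature_protein
        peaks, truth = simulate_spectrum(protein, "trypsin", config, chain="light")
        expected = sorted({p.mh_mono for p in digest(protein, "trypsin", chain="light")})
        assert peaks.mz == expected
        assert {p.sequence for p in truth} == {p.sequence for p in digest(protein, "trypsin")}

    def test_full_dropout_leaves_only_noise(self, world):
        config = FixtureConfig(seed=4, peak_dropout=1.0, n_noise_peaks=7)
        peaks, truth = simulate_spectrum(world.truth.kappa_mature_protein,
                                         "acid", config, chain="light")
        assert truth == []
        assert len(peaks.peaks) == 7

    def test_seeded_runs_reproduce(self, world):
        config = FixtureConfig(seed=9)
        a, _ = simulate_spectrum(world.truth.heavy_mature_protein, "acid", config)
        b, _ = simulate_spectrum(world.truth.heavy_mature_protein, "acid", config)
        assert a.peaks == b.peaks
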