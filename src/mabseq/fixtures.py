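"""Synthetic ground-truth fixtures for the whole workflow.

Everything the pipeline consumes can be generated here with known
truth: germline mini-references, full antibody mRNA architectures
(leader + V-(D-)J + constant exons + 3'UTR + poly-A), clone read sets
with a planted aberrant kappa variant, CH1 references carrying
subclass-discriminative columns and primer binding sites, strain
constant-region references differing by the CH3 dinucleotide swap, and
simulated MALDI peak lists.

The sequences are synthetic but structurally faithful: in-frame coding
regions, a conserved FR3 cysteine anchor ending each germline V, J
segments beginning with the canonical [FW]-G-x-G framework-4 motif,
and CH1 exons that are identical across subclasses except at the
engineered discriminative columns.  The aberrant kappa transcript is
modelled on the well-known myeloma fusion-partner chains (MOPC21
lineage): a *different* germline V rearrangement whose V-J junction
carries a 1-nt deletion producing a premature stop codon shortly after
the junction.  Reference records that stand in for curated database
entries are synthetic and named accordingly.

A single seed drives all randomness; identical seed + config give
byte-identical outputs.  The generator validates its own construction
(motif exclusivity in the amplicons, planted primer mismatch counts,
junction uniqueness) and, because those guarantees involve random
sequence, retries with a derived sub-seed until they hold -- the
result is still a pure function of (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .align import STOP_CODONS, global_identity, overlap_identity, revcomp
from .errors import ValidationError
from .fingerprint import TheoreticalPeptide, digest
from .io import NucleotideRead, PeakList, PrimerRecord, ReferenceRecord
from .isotyping import derive_motifs, scan_primer_sites

SUBCLASSES = ("IgG1", "IgG2a", "IgG2b", "IgG2c", "IgG3")
STRAINS = ("C57BL/6J", "NOD")

# Clone-specific CDR3 junctions embedded by default (heavy V-D-J and
# kappa V-J nucleotide junctions of the worked example).
HEAVY_CDR3_NT = "GTCAGATACGGTGGTGGAGGGTTTGCTTAC"
KAPPA_CDR3_NT = "CAGCAGTATCATAGTTACCCACGGACG"

# kappa FR4 with codons chosen so that a 1-nt deletion at the V-J
# junction reads through to a TAA stop nine codons downstream
KAPPA_FR4_NT = "TTTGGACAAGGTACCAAGCTCGAAATAAAA"  # FGQGTKLEIK
HEAVY_FR4_AA = "WGQGTLVTVSA"

ISPCR = "AAGCAGTGGTATCAACGCAGAGT"
TSO = ISPCR + "ACATGGG"
OLIGO_DT_ANCHOR = ISPCR + "T" * 30

_AA_POOL = "ADEFGHIKLMNPQRSTVY"          # no Cys/Trp: anchors stay unambiguous
_AA_POOL_CDR = "ADEFGHILMNQSTVY"         # additionally no Lys/Arg/Pro inside CDR1/2
_CODON_OF = {}
for _c in [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]:
    _aa = str(Seq(_c).translate())
    _CODON_OF.setdefault(_aa, []).append(_c)


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions emulated by the generator."""

    seed: int = 0
    n_reads_per_chain: int = 8
    read_error_rate: float = 0.001
    aberrant_fraction: float = 0.5
    subclass: str = "IgG2c"
    strain: str = "NOD"
    peak_dropout: float = 0.2
    mz_jitter_ppm: float = 15.0
    n_noise_peaks: int = 10

    def __post_init__(self):
        for name in ("read_error_rate", "aberrant_fraction", "peak_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.subclass not in SUBCLASSES:
            raise ValidationError(f"unknown subclass {self.subclass!r}")
        if self.strain not in STRAINS:
            raise ValidationError(f"unknown strain {self.strain!r}")


@dataclass
class FixtureTruth:
    """Ground truth recorded while building the templates."""

    heavy_regions: dict[str, tuple[int, int]]
    kappa_regions: dict[str, tuple[int, int]]
    heavy_amplicon: tuple[int, int]
    kappa_amplicon: tuple[int, int]
    aberrant_amplicon_seq: str
    heavy_cdr3_nt: str
    kappa_cdr3_nt: str
    subclass: str
    strain: str
    heavy_mature_protein: str
    kappa_mature_protein: str
    vh_aa_len: int
    vl_aa_len: int
    expected_heavy_product_nt: int
    expected_kappa_product_nt: int
    heavy_cdr_spans_aa: dict[str, tuple[int, int]]
    kappa_cdr_spans_aa: dict[str, tuple[int, int]]
    strain_swap_position_aa: int


@dataclass
class FixtureWorld:
    """All generated inputs plus their ground truth."""

    config: FixtureConfig
    heavy_mrna: str
    kappa_mrna: str
    aberrant_mrna: str
    truth: FixtureTruth
    references: dict[str, list[ReferenceRecord]]
    primers: list[PrimerRecord]
    ch1_by_subclass: dict[str, str]


# ---------------------------------------------------------------- helpers

def _rand_protein(rng, n, pool=_AA_POOL):
    return "".join(pool[i] for i in rng.integers(0, len(pool), n))


def _revtrans(rng, protein):
    out = []
    for aa in protein:
        codons = _CODON_OF[aa]
        out.append(codons[rng.integers(0, len(codons))])
    return "".join(out)


def _rand_dna(rng, n, pool="ACGT"):
    return "".join(pool[i] for i in rng.integers(0, len(pool), n))


def _utr5(rng, n=30):
    seq = _rand_dna(rng, n)
    while "ATG" in seq:
        seq = seq.replace("ATG", "ATC", 1)
    return seq


def _utr3(rng, n):
    # tail kept A-free so the poly-A tract boundary is exact
    return _rand_dna(rng, n - 20) + _rand_dna(rng, 20, pool="CGT")


class _ScrubFailed(Exception):
    """Motif scrubbing could not find a safe substitution; rebuild the world."""


def _scrub_motifs(
    seq: str,
    probes: set[str],
    rng,
    coding: bool = False,
    forbid: tuple[tuple[int, int], ...] = (),
    allowed_codons: list[int] | None = None,
    no_atg: bool = False,
    tail_no_a: int = 0,
    max_iter: int = 200,
) -> tuple[str, list[tuple[int, str]]]:
    """Remove exact motif occurrences (either strand) by point substitutions.

    The isotype caller scans consensus sequences for subclass motifs, so
    the random, non-CH1 template parts must not contain any of them by
    chance.  Substitutions avoid stop codons in coding sequence, never
    touch forbidden ranges (engineered anchors, fixed junctions), and
    optionally avoid creating ATG (5'UTRs) or A in the tail (3'UTRs).
    """
    forbidden: set[int] = set()
    for lo, hi in forbid:
        forbidden.update(range(lo, hi))
    if allowed_codons is not None:
        allowed = {3 * c + k for c in allowed_codons for k in range(3)}
        forbidden |= set(range(len(seq))) - allowed
    edits: list[tuple[int, str]] = []
    for _ in range(max_iter):
        hit = None
        for probe in probes:
            p = seq.find(probe)
            if p >= 0:
                hit = (p, len(probe))
                break
        if hit is None:
            return seq, edits
        p, length = hit
        candidates = [i for i in range(p, p + length) if i not in forbidden]
        if not candidates:
            raise _ScrubFailed
        pos = candidates[int(rng.integers(0, len(candidates)))]
        base = _pick_base(seq, pos, rng, coding=coding, no_atg=no_atg,
                          tail_no_a=tail_no_a)
        if base is None:
            raise _ScrubFailed
        seq = seq[:pos] + base + seq[pos + 1:]
        edits.append((pos, base))
    raise _ScrubFailed


def _pick_base(seq, pos, rng, coding, no_atg, tail_no_a):
    order = list("ACGT")
    rng.shuffle(order)
    codon_start = pos - pos % 3
    for base in order:
        if base == seq[pos]:
            continue
        if tail_no_a and pos >= len(seq) - tail_no_a and base == "A":
            continue
        cand = seq[:pos] + base + seq[pos + 1:]
        if coding and cand[codon_start:codon_start + 3] in STOP_CODONS:
            continue
        if no_atg and "ATG" in cand[max(0, pos - 2):pos + 3]:
            continue
        return base
    return None


def _both_strands(motifs: list[str]) -> set[str]:
    return set(motifs) | {revcomp(m) for m in motifs}


def _substitute_avoid_stop(seq: str, pos: int) -> str:
    codon_start = pos - pos % 3
    for base in "ACGT":
        if base == seq[pos]:
            continue
        cand = seq[:pos] + base + seq[pos + 1:]
        if cand[codon_start:codon_start + 3] not in STOP_CODONS:
            return cand
    raise AssertionError("unreachable: some substitution avoids a stop")


def _mutate_coding(rng, seq: str, n_subs: int, allowed_codons: list[int]) -> str:
    """Plant substitutions (somatic-hypermutation style) in allowed codons."""
    chosen = rng.choice(len(allowed_codons), size=n_subs, replace=False)
    for idx in chosen:
        codon = allowed_codons[idx]
        pos = 3 * codon + int(rng.integers(0, 3))
        seq = _substitute_avoid_stop(seq, pos)
    return seq


def _edit(protein: str, pos1: int, residue: str) -> str:
    return protein[:pos1 - 1] + residue + protein[pos1:]


# ------------------------------------------------------------ world build

def build_world(config: FixtureConfig, max_attempts: int = 50) -> FixtureWorld:
    """Build the full fixture world for a configuration (deterministic)."""
    for attempt in range(max_attempts):
        rng = np.random.default_rng([int(config.seed) % 2**31, attempt])
        try:
            world = _build_once(rng, config)
        except _ScrubFailed:
            continue
        if _validate_world(world):
            return world
    raise ValidationError("fixture generation failed validation after retries")


def _build_once(rng, config: FixtureConfig) -> FixtureWorld:
    # --- variable regions -------------------------------------------------
    vh_fr = _rand_protein(rng, 96)
    vh_fr = _edit(vh_fr, 25, "K")
    vh_fr = vh_fr[:25] + _rand_protein(rng, 8, _AA_POOL_CDR) + vh_fr[33:]   # CDR-H1 26-33
    vh_fr = _edit(vh_fr, 34, _AA_POOL_CDR[rng.integers(0, len(_AA_POOL_CDR))])
    vh_fr = _edit(vh_fr, 50, "K")
    vh_fr = vh_fr[:50] + _rand_protein(rng, 8, _AA_POOL_CDR) + vh_fr[58:]   # CDR-H2 51-58
    vh_fr = _edit(vh_fr, 59, _AA_POOL_CDR[rng.integers(0, len(_AA_POOL_CDR))])
    vh_fr = _edit(vh_fr, 95, "K")
    vh_fr = _edit(vh_fr, 96, "C")
    vh_germline_nt = _revtrans(rng, vh_fr)
    free_codons_h = [i for i in range(96) if not (23 <= i <= 35 or 48 <= i <= 59 or i >= 93)]
    vh_sample_nt = _mutate_coding(rng, vh_germline_nt, 4, free_codons_h)

    vl_fr = _rand_protein(rng, 88)
    vl_fr = _edit(vl_fr, 23, "K")
    vl_fr = vl_fr[:23] + _rand_protein(rng, 11, _AA_POOL_CDR) + vl_fr[34:]  # CDR-L1 24-34
    vl_fr = _edit(vl_fr, 35, _AA_POOL_CDR[rng.integers(0, len(_AA_POOL_CDR))])
    vl_fr = _edit(vl_fr, 49, "K")
    vl_fr = vl_fr[:49] + _rand_protein(rng, 7, _AA_POOL_CDR) + vl_fr[56:]   # CDR-L2 50-56
    vl_fr = _edit(vl_fr, 57, _AA_POOL_CDR[rng.integers(0, len(_AA_POOL_CDR))])
    vl_fr = _edit(vl_fr, 87, "K")
    vl_fr = _edit(vl_fr, 88, "C")
    vl_germline_nt = _revtrans(rng, vl_fr)
    free_codons_l = [i for i in range(88) if not (21 <= i <= 36 or 47 <= i <= 57 or i >= 85)]
    vl_sample_nt = _mutate_coding(rng, vl_germline_nt, 2, free_codons_l)

    # aberrant kappa: a different germline rearrangement (fusion-partner type)
    vl_ab_fr = _edit(_edit(_rand_protein(rng, 88), 87, "K"), 88, "C")
    vl_aberrant_nt = _revtrans(rng, vl_ab_fr)
    cdr3_ab_nt = _revtrans(rng, _rand_protein(rng, 9, _AA_POOL_CDR))

    fr4_h_nt = _revtrans(rng, HEAVY_FR4_AA)
    fr4_k_nt = KAPPA_FR4_NT
    fr4_k_del = fr4_k_nt[1:]                       # the 1-nt junction deletion

    # --- constant regions -------------------------------------------------
    ch1_prot = _edit(_rand_protein(rng, 98), 5, "K")
    if ch1_prot[5] == "P":
        ch1_prot = _edit(ch1_prot, 6, "A")
    ch1_base = _revtrans(rng, ch1_prot)
    ch1 = _make_ch1_set(ch1_base)

    hinge_nt = _revtrans(rng, _rand_protein(rng, 15))
    ch2_nt = _revtrans(rng, _rand_protein(rng, 110))
    ch3_prot = _rand_protein(rng, 106)
    ch3_nt = _revtrans(rng, ch3_prot)
    # CH3 codon 95 carries the strain-discriminating dinucleotide swap:
    # NOD glycine GGT vs C57BL/6J valine GTG (TG <-> GT)
    ch3_nod = ch3_nt[:282] + "GGT" + ch3_nt[285:]
    ch3_c57 = ch3_nt[:282] + "GTG" + ch3_nt[285:]
    ch3_sample = ch3_nod if config.strain == "NOD" else ch3_c57

    cl_prot = _rand_protein(rng, 107)
    if cl_prot[0] == "P":
        cl_prot = _edit(cl_prot, 1, "A")
    cl_nt = _revtrans(rng, cl_prot)

    igl1_nt = _revtrans(rng, _rand_protein(rng, 105))
    igl2_nt = _revtrans(rng, _rand_protein(rng, 105))

    # --- leaders and UTRs -------------------------------------------------
    leader_h = "ATG" + _revtrans(rng, _rand_protein(rng, 18))   # 57 nt
    leader_k = "ATG" + _revtrans(rng, _rand_protein(rng, 19))   # 60 nt
    leader_a = "ATG" + _revtrans(rng, _rand_protein(rng, 19))
    utr5_h, utr5_k, utr5_a = _utr5(rng), _utr5(rng), _utr5(rng)
    utr3_h, utr3_k, utr3_a = _utr3(rng, 194), _utr3(rng, 166), _utr3(rng, 166)

    # --- motif scrubbing --------------------------------------------------
    # subclass motifs must not occur by chance in any random template part
    # that ends up in a variable-region consensus
    ch1_refs = [ReferenceRecord(f"IGHG-{s}-CH1", ch1[s], "CH1_exon",
                                subclass_or_strain=s) for s in SUBCLASSES]
    probes = _both_strands([m for _, m, _ in derive_motifs(ch1_refs).all_motifs()])
    utr5_h, _ = _scrub_motifs(utr5_h, probes, rng, no_atg=True)
    utr5_k, _ = _scrub_motifs(utr5_k, probes, rng, no_atg=True)
    utr5_a, _ = _scrub_motifs(utr5_a, probes, rng, no_atg=True)
    utr3_h, _ = _scrub_motifs(utr3_h, probes, rng, tail_no_a=20)
    utr3_k, _ = _scrub_motifs(utr3_k, probes, rng, tail_no_a=20)
    utr3_a, _ = _scrub_motifs(utr3_a, probes, rng, tail_no_a=20)
    leader_h, _ = _scrub_motifs(leader_h, probes, rng, coding=True, forbid=((0, 3),))
    leader_k, _ = _scrub_motifs(leader_k, probes, rng, coding=True, forbid=((0, 3),))
    leader_a, _ = _scrub_motifs(leader_a, probes, rng, coding=True, forbid=((0, 3),))
    # sample V edits are mirrored into the germline so the planted somatic
    # mutation count (and hence the identity percentage) is preserved
    vh_sample_nt, edits = _scrub_motifs(vh_sample_nt, probes, rng, coding=True,
                                        allowed_codons=free_codons_h)
    for pos, base in edits:
        vh_germline_nt = vh_germline_nt[:pos] + base + vh_germline_nt[pos + 1:]
    vl_sample_nt, edits = _scrub_motifs(vl_sample_nt, probes, rng, coding=True,
                                        allowed_codons=free_codons_l)
    for pos, base in edits:
        vl_germline_nt = vl_germline_nt[:pos] + base + vl_germline_nt[pos + 1:]
    vl_aberrant_nt, _ = _scrub_motifs(vl_aberrant_nt, probes, rng, coding=True,
                                      forbid=((258, 264),))
    cdr3_ab_nt, _ = _scrub_motifs(cdr3_ab_nt, probes, rng, coding=True)
    fr4_h_nt, _ = _scrub_motifs(fr4_h_nt, probes, rng, coding=True, forbid=((0, 3),))
    cl_nt, _ = _scrub_motifs(cl_nt, probes, rng, coding=True, forbid=((0, 3),))

    # --- assembled mRNAs --------------------------------------------------
    constant_h = ch1[config.subclass] + hinge_nt + ch2_nt + ch3_sample
    heavy_mrna = (utr5_h + leader_h + vh_sample_nt + HEAVY_CDR3_NT + fr4_h_nt
                  + constant_h + "TAA" + utr3_h + "A" * 30)
    kappa_mrna = (utr5_k + leader_k + vl_sample_nt + KAPPA_CDR3_NT + fr4_k_nt
                  + cl_nt + "TAA" + utr3_k + "A" * 30)
    aberrant_mrna = (utr5_a + leader_a + vl_aberrant_nt + cdr3_ab_nt + fr4_k_del
                     + cl_nt + "TAA" + utr3_a + "A" * 30)

    h_regions = _cumulative_regions([
        ("5'UTR", 30), ("leader", 57), ("V", 288), ("CDR3", 30), ("FR4", 33),
        ("CH1", 294), ("hinge", 45), ("CH2", 330), ("CH3", 318),
        ("stop", 3), ("3'UTR", 194), ("polyA", 30),
    ])
    k_regions = _cumulative_regions([
        ("5'UTR", 30), ("leader", 60), ("V", 264), ("CDR3", 27), ("FR4", 30),
        ("CL", 321), ("stop", 3), ("3'UTR", 166), ("polyA", 30),
    ])
    # variable-region amplicons end at the chain-specific reverse primer site
    heavy_amplicon = (0, h_regions["CH1"][0] + 122)
    kappa_amplicon = (0, k_regions["CL"][0] + 142)
    ab_amplicon_end = 30 + 60 + 264 + 27 + 29 + 142
    aberrant_amplicon_seq = aberrant_mrna[:ab_amplicon_end]

    heavy_mature = str(Seq(heavy_mrna[h_regions["V"][0]:h_regions["stop"][0]]).translate())
    kappa_mature = str(Seq(kappa_mrna[k_regions["V"][0]:k_regions["stop"][0]]).translate())

    truth = FixtureTruth(
        heavy_regions=h_regions,
        kappa_regions=k_regions,
        heavy_amplicon=heavy_amplicon,
        kappa_amplicon=kappa_amplicon,
        aberrant_amplicon_seq=aberrant_amplicon_seq,
        heavy_cdr3_nt=HEAVY_CDR3_NT,
        kappa_cdr3_nt=KAPPA_CDR3_NT,
        subclass=config.subclass,
        strain=config.strain,
        heavy_mature_protein=heavy_mature,
        kappa_mature_protein=kappa_mature,
        vh_aa_len=117,
        vl_aa_len=107,
        expected_heavy_product_nt=(h_regions["polyA"][0] - h_regions["CDR3"][0]
                                   + len(OLIGO_DT_ANCHOR)),
        expected_kappa_product_nt=(k_regions["polyA"][0] - k_regions["CDR3"][0]
                                   + len(OLIGO_DT_ANCHOR)),
        heavy_cdr_spans_aa={"CDR1": (26, 33), "CDR2": (51, 58), "CDR3": (97, 106)},
        kappa_cdr_spans_aa={"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
        strain_swap_position_aa=117 + 318,
    )

    references = {
        "germline_V_heavy": [
            ReferenceRecord("IGHV-2*01", vh_germline_nt, "germline_V"),
            ReferenceRecord("IGHV2-6-8*01", vh_germline_nt, "germline_V"),
            ReferenceRecord("IGHV5-17*01", _revtrans(rng, _edit(_rand_protein(rng, 96), 96, "C")), "germline_V"),
        ],
        "germline_D": [
            ReferenceRecord("IGHD-1*01", HEAVY_CDR3_NT[6:21], "germline_D"),
            ReferenceRecord("IGHD-1*02", HEAVY_CDR3_NT[6:21], "germline_D"),
            ReferenceRecord("IGHD-2*01", _rand_dna(rng, 15), "germline_D"),
        ],
        "germline_J_heavy": [ReferenceRecord("IGHJ3*01", fr4_h_nt, "germline_J")],
        "germline_V_kappa": [
            ReferenceRecord("IGKV4-61*01", vl_germline_nt, "germline_V"),
            ReferenceRecord("IGKV12-41*01", vl_aberrant_nt, "germline_V"),
        ],
        "germline_J_kappa": [ReferenceRecord("IGKJ1*01", fr4_k_nt, "germline_J")],
        "CH1_exon": [
            ReferenceRecord(f"IGHG-{s}-CH1", ch1[s], "CH1_exon", subclass_or_strain=s)
            for s in SUBCLASSES
        ],
        "constant_heavy_strain": [
            ReferenceRecord("IGHG2c-C57BL6J", ch1["IgG2c"] + hinge_nt + ch2_nt + ch3_c57,
                            "constant_region", subclass_or_strain="C57BL/6J"),
            ReferenceRecord("IGHG2c-NOD", ch1["IgG2c"] + hinge_nt + ch2_nt + ch3_nod,
                            "constant_region", subclass_or_strain="NOD"),
        ],
        "constant_light": [
            ReferenceRecord("IGKC", cl_nt, "constant_region", subclass_or_strain="kappa"),
            ReferenceRecord("IGLC1", igl1_nt, "constant_region", subclass_or_strain="IgLC1"),
            ReferenceRecord("IGLC2", igl2_nt, "constant_region", subclass_or_strain="IgLC2"),
        ],
        "aberrant_kappa": [
            ReferenceRecord("nonfunctional-kappa-synthetic-1", aberrant_amplicon_seq, "aberrant_kappa"),
            ReferenceRecord("nonfunctional-kappa-synthetic-2",
                            _revtrans(rng, _rand_protein(rng, 180)), "aberrant_kappa"),
        ],
    }

    primers = [
        PrimerRecord("ISPCR", ISPCR, "PCR"),
        PrimerRecord("TSO", TSO, "template_switch"),
        PrimerRecord("AOligo(dT)-ISPCR", OLIGO_DT_ANCHOR, "oligo_dT_anchor"),
        PrimerRecord("mIGHG-RT", revcomp(ch1["IgG1"][100:122]), "RT"),
        PrimerRecord("mIGHG-PCR", revcomp(ch1["IgG1"][55:77]), "PCR"),
        PrimerRecord("mIGK-RT", revcomp(cl_nt[120:142]), "RT"),
        PrimerRecord("mIGK-PCR", revcomp(cl_nt[118:140]), "PCR"),
        PrimerRecord("mIGL-RT", _lambda_primer(igl1_nt), "RT"),
    ]

    return FixtureWorld(
        config=config,
        heavy_mrna=heavy_mrna,
        kappa_mrna=kappa_mrna,
        aberrant_mrna=aberrant_mrna,
        truth=truth,
        references=references,
        primers=primers,
        ch1_by_subclass=ch1,
    )


def _make_ch1_set(base: str) -> dict[str, str]:
    """Plant discriminative columns and primer-site mismatches in CH1.

    Columns 33/34 (1-based) carry a subclass-specific base pair inside
    codons that cannot become stops; the IgG3 reverse-transcription site
    (nt 101-122) carries five substitutions and the PCR site (nt 56-77)
    one substitution in IgG2b and four in IgG3, reproducing the primer
    binding-site mismatch pattern of the published primer set.
    """
    pair = {"IgG1": "AA", "IgG2a": "CC", "IgG2b": "GG", "IgG2c": "TT", "IgG3": "AC"}
    out = {}
    for subclass in SUBCLASSES:
        x, y = pair[subclass]
        seq = base[:30] + "CC" + x + y + "CT" + base[36:]
        if subclass == "IgG2b":
            seq = _substitute_avoid_stop(seq, 66)
        if subclass == "IgG3":
            for pos in (57, 62, 68, 74):            # PCR site, 4 mismatches
                seq = _substitute_avoid_stop(seq, pos)
            for pos in (102, 106, 110, 115, 119):   # RT site, 5 mismatches
                seq = _substitute_avoid_stop(seq, pos)
        out[subclass] = seq
    return out


def _lambda_primer(igl1: str) -> str:
    """Lambda RT primer with one planted mismatch vs IgLC1 (less conserved site)."""
    site = igl1[100:122]
    probe = _substitute_avoid_stop(site, 10)
    return revcomp(probe)


def _cumulative_regions(parts: list[tuple[str, int]]) -> dict[str, tuple[int, int]]:
    regions, pos = {}, 0
    for label, length in parts:
        regions[label] = (pos, pos + length)
        pos += length
    return regions


def _validate_world(world: FixtureWorld) -> bool:
    """Seed-independent guarantees that involve random sequence."""
    truth = world.truth
    # CDR3 anchors occur exactly once in their templates
    if world.heavy_mrna.count(truth.heavy_cdr3_nt) != 1:
        return False
    if world.kappa_mrna.count(truth.kappa_cdr3_nt) != 1:
        return False
    # planted primer mismatch pattern survives the minimum-Hamming scan
    ch1_refs = world.references["CH1_exon"]
    rt = next(p for p in world.primers if p.name == "mIGHG-RT")
    pcr = next(p for p in world.primers if p.name == "mIGHG-PCR")
    rt_mm = {r.reference_id: r.mismatches for r in scan_primer_sites(rt, ch1_refs)}
    pcr_mm = {r.reference_id: r.mismatches for r in scan_primer_sites(pcr, ch1_refs)}
    expected_rt = {"IgG1": 0, "IgG2a": 0, "IgG2b": 0, "IgG2c": 0, "IgG3": 5}
    expected_pcr = {"IgG1": 0, "IgG2a": 0, "IgG2b": 1, "IgG2c": 0, "IgG3": 4}
    for s in SUBCLASSES:
        if rt_mm[f"IGHG-{s}-CH1"] != expected_rt[s] or pcr_mm[f"IGHG-{s}-CH1"] != expected_pcr[s]:
            return False
    # no subclass motif may occur outside its own CH1 in any amplicon
    try:
        motifs = derive_motifs(ch1_refs)
    except ValidationError:
        return False
    all_motifs = list(motifs.all_motifs())
    kappa_amp = world.kappa_mrna[slice(*truth.kappa_amplicon)]
    kappa_texts = [kappa_amp, revcomp(kappa_amp),
                   truth.aberrant_amplicon_seq, revcomp(truth.aberrant_amplicon_seq)]
    # kappa amplicons must stay motif-free entirely
    if any(motif in t for _, motif, _ in all_motifs for t in kappa_texts):
        return False
    for subclass in SUBCLASSES:
        amp = _heavy_amplicon_for(world, subclass)
        for other, motif, _ in all_motifs:
            if other != subclass and (motif in amp or motif in revcomp(amp)):
                return False
    # the two kappa variants must be clearly separable
    if global_identity(kappa_amp, truth.aberrant_amplicon_seq) > 0.90:
        return False
    # light-class margins: only the kappa amplicon resembles the kappa CL
    lights = {r.id: r.sequence for r in world.references["constant_light"]}
    heavy_amp = world.heavy_mrna[slice(*truth.heavy_amplicon)]
    if overlap_identity(heavy_amp, lights["IGKC"]) > 0.85:
        return False
    if any(overlap_identity(kappa_amp, lights[i]) > 0.85 for i in ("IGLC1", "IGLC2")):
        return False
    return True


def _heavy_amplicon_for(world: FixtureWorld, subclass: str) -> str:
    """Heavy variable-region amplicon rebuilt with a given subclass CH1 stub."""
    lo, hi = world.truth.heavy_amplicon
    ch1_start = world.truth.heavy_regions["CH1"][0]
    return (world.heavy_mrna[lo:ch1_start]
            + world.ch1_by_subclass[subclass][: hi - ch1_start])


# ----------------------------------------------------------- public ops

def make_antibody_template(config: FixtureConfig) -> tuple[str, str, FixtureTruth]:
    """Heavy and kappa mRNA templates plus their ground-truth annotation."""
    world = build_world(config)
    return world.heavy_mrna, world.kappa_mrna, world.truth


def make_clone_reads(
    world: FixtureWorld,
    chain: str,
    config: FixtureConfig | None = None,
) -> tuple[list[NucleotideRead], dict[str, str]]:
    """Simulated Sanger clone reads for one chain, with truth labels.

    Kappa read sets mix the productive transcript with the aberrant
    fusion-partner transcript at ``aberrant_fraction`` (which times the
    read count must be integral); heavy read sets are homogeneous.
    Substitution errors are planted iid at ``read_error_rate``.
    """
    config = config or world.config
    n = config.n_reads_per_chain
    if chain == "heavy":
        templates = [world.heavy_mrna[slice(*world.truth.heavy_amplicon)]] * n
        labels = ["productive"] * n
        prefix, salt = "H", 1
    elif chain == "kappa":
        n_ab = config.aberrant_fraction * n
        if abs(n_ab - round(n_ab)) > 1e-9:
            raise ValidationError("aberrant_fraction x n_reads must be integral")
        n_ab = round(n_ab)
        productive = world.kappa_mrna[slice(*world.truth.kappa_amplicon)]
        aberrant = world.truth.aberrant_amplicon_seq
        templates = [aberrant] * n_ab + [productive] * (n - n_ab)
        labels = ["aberrant"] * n_ab + ["productive"] * (n - n_ab)
        prefix, salt = "K", 2
    else:
        raise ValidationError(f"unknown chain {chain!r}")

    rng = np.random.default_rng([int(config.seed) % 2**31, salt])
    order = rng.permutation(n)
    reads, truth_labels = [], {}
    for rank, idx in enumerate(order, start=1):
        seq = _add_errors(rng, templates[idx], config.read_error_rate)
        read_id = f"{prefix}{rank:02d}"
        reads.append(NucleotideRead(id=read_id, sequence=seq, chain_hint=chain))
        truth_labels[read_id] = labels[idx]
    return reads, truth_labels


def make_constant_reads(
    world: FixtureWorld,
    chain: str,
    config: FixtureConfig | None = None,
) -> list[NucleotideRead]:
    """Clone reads of the step-2 constant-region amplicon (CDR3 to poly-A)."""
    config = config or world.config
    if chain == "heavy":
        lo = world.truth.heavy_regions["CDR3"][0]
        hi = world.truth.heavy_regions["polyA"][0]
        template, prefix, salt = world.heavy_mrna[lo:hi], "CH", 5
    elif chain == "kappa":
        lo = world.truth.kappa_regions["CDR3"][0]
        hi = world.truth.kappa_regions["polyA"][0]
        template, prefix, salt = world.kappa_mrna[lo:hi], "CK", 6
    else:
        raise ValidationError(f"unknown chain {chain!r}")
    rng = np.random.default_rng([int(config.seed) % 2**31, salt])
    return [
        NucleotideRead(id=f"{prefix}{i:02d}",
                       sequence=_add_errors(rng, template, config.read_error_rate),
                       chain_hint=chain)
        for i in range(1, config.n_reads_per_chain + 1)
    ]


def _add_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_spectrum(
    protein: str,
    mode: str,
    config: FixtureConfig,
    chain: str = "heavy",
    max_missed: int | None = None,
) -> tuple[PeakList, list[TheoreticalPeptide]]:
    """Simulated MALDI peak list from an in-silico digest.

    Each theoretical peak survives with probability 1 - peak_dropout,
    its m/z is jittered by N(0, mz_jitter_ppm), and uniform decoy noise
    peaks are added across the observed range.  The surviving peptides
    are returned as truth.
    """
    peptides = digest(protein, mode, max_missed=max_missed, chain=chain)
    salt = 3 if mode == "trypsin" else 4
    rng = np.random.default_rng([int(config.seed) % 2**31, salt, len(protein)])
    surviving, peaks = [], {}
    for pep in peptides:
        if rng.random() < config.peak_dropout:
            continue
        mz = pep.mh_mono * (1.0 + rng.normal(0.0, config.mz_jitter_ppm) * 1e-6)
        peaks[mz] = peaks.get(mz, 0.0) + float(rng.uniform(20.0, 100.0))
        surviving.append(pep)
    if peaks:
        lo, hi = min(peaks), max(peaks)
    else:
        lo, hi = 800.0, 4000.0
    for _ in range(config.n_noise_peaks):
        peaks[float(rng.uniform(lo, hi))] = float(rng.uniform(1.0, 20.0))
    ordered = sorted(peaks.items())
    return (
        PeakList(peaks=[(m, i) for m, i in ordered],
                 source_label=f"simulated-{mode}", cleavage_mode=mode),
        surviving,
    )


def make_cdr_benchmark_peaklists(
    world: FixtureWorld,
    exclude_label: str = "H-CDR2",
) -> tuple[dict[str, PeakList], list[TheoreticalPeptide]]:
    """Noise-free spectra covering every CDR except one.

    Pools trypsin and acid digests of the mature heavy and light chains
    and removes every peptide that fully contains the excluded CDR, so
    the fingerprint stage should assign exactly five of the six CDRs.
    """
    spans = _all_cdr_spans(world)
    excluded = spans[exclude_label]
    theoreticals: list[TheoreticalPeptide] = []
    for chain, protein in (("heavy", world.truth.heavy_mature_protein),
                           ("light", world.truth.kappa_mature_protein)):
        for mode in ("trypsin", "acid"):
            theoreticals.extend(digest(protein, mode, chain=chain))
    kept = [
        p for p in theoreticals
        if not (p.chain == excluded[0] and p.start <= excluded[1] and excluded[2] <= p.end)
    ]
    peaklists = {}
    for mode in ("trypsin", "acid"):
        mz = sorted({p.mh_mono for p in kept if p.cleavage_mode == mode})
        peaklists[mode] = PeakList(
            peaks=[(m, 50.0) for m in mz], source_label=f"benchmark-{mode}",
            cleavage_mode=mode,
        )
    return peaklists, kept


def _all_cdr_spans(world: FixtureWorld) -> dict[str, tuple[str, int, int]]:
    spans = {}
    for label, (s, e) in world.truth.heavy_cdr_spans_aa.items():
        spans[f"H-{label}"] = ("heavy", s, e)
    for label, (s, e) in world.truth.kappa_cdr_spans_aa.items():
        spans[f"L-{label}"] = ("light", s, e)
    return spans
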