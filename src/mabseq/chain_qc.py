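"""Productive-vs-aberrant transcript QC and strain comparison.

Hybridoma lines frequently co-express a non-functional immunoglobulin
transcript inherited from the myeloma fusion partner; the classic
example is a kappa chain with a frameshift at the V-J junction that
introduces a premature stop codon.  This module decides whether a
consensus transcript is productive, matches it against known
non-functional references, and compares constant regions between mouse
strains (e.g. C57BL/6J vs NOD IgG2c, which differ by a single
dinucleotide swap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .align import align_global, global_identity
from .errors import ValidationError
from .io import ReferenceRecord

log = logging.getLogger(__name__)


@dataclass
class OrfReport:
    """Reading-frame analysis of one consensus transcript."""

    frame_offset: int
    protein: str
    premature_stop: bool
    stop_position_aa: int | None
    leader_detected: bool
    start_nt: int


@dataclass
class AberranceCall:
    flagged: bool
    reason: str
    best_ref_id: str | None = None
    best_identity: float | None = None
    orf: OrfReport | None = None


@dataclass
class StrainComparison:
    """Nucleotide/amino-acid differences between sample and one reference."""

    strain_a_id: str
    strain_b_id: str
    nt_differences: list[tuple[int, str, str]] = field(default_factory=list)
    aa_differences: list[tuple[int, str, str]] = field(default_factory=list)


def annotate_orf(
    consensus: str,
    atg_window: int = 90,
    min_open_aa: int = 30,
    premature_fraction: float = 0.9,
    expected_len_nt: int | None = None,
) -> OrfReport:
    """Pick the reading frame and flag premature stop codons.

    The ORF is anchored at an ATG within the first ``atg_window`` nt
    (captures the natural secretion-leader start); if none exists, the
    three frame starts are tried instead.  Among candidates the longest
    stop-free stretch wins.  A stop is *premature* when it occurs before
    ``premature_fraction`` of the expected chain length (taken from the
    consensus 3' end unless ``expected_len_nt`` is given), which is far
    upstream for junction-frameshift chains.
    """
    if len(consensus) < 60:
        raise ValidationError("consensus shorter than 60 nt")
    starts = [i for i in range(min(atg_window, len(consensus) - 2)) if consensus[i:i + 3] == "ATG"]
    leader_detected = bool(starts)
    if not starts:
        starts = [0, 1, 2]

    best = None  # (open_len, -start, start, protein, stop_aa)
    for start in starts:
        protein, stop_aa = _translate_until_stop(consensus, start)
        cand = (len(protein), -start, start, protein, stop_aa)
        if best is None or cand > best:
            best = cand
    _, _, start, protein, stop_aa = best

    total_aa = (((expected_len_nt or len(consensus)) - start) // 3)
    premature = stop_aa is not None and stop_aa < premature_fraction * total_aa
    if len(protein) < min_open_aa:
        premature = True
        log.info("likely aberrant: longest open stretch is only %d aa", len(protein))
    return OrfReport(
        frame_offset=start % 3,
        protein=protein,
        premature_stop=premature,
        stop_position_aa=stop_aa,
        leader_detected=leader_detected,
        start_nt=start,
    )


def _translate_until_stop(consensus: str, start: int) -> tuple[str, int | None]:
    coding = consensus[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stop = aa.find("*")
    if stop == -1:
        return aa, None
    return aa[:stop], stop + 1


def flag_aberrant(
    consensus: str,
    aberrant_refs: list[ReferenceRecord],
    min_identity: float = 0.95,
    orf: OrfReport | None = None,
) -> AberranceCall:
    """Flag a consensus as aberrant by reference match or premature stop.

    True iff global-alignment identity to any known non-functional
    reference reaches ``min_identity`` *or* the ORF report carries a
    premature stop.  Monotone in ``min_identity``: raising the threshold
    can only lose the identity branch, never gain it.
    """
    if not aberrant_refs:
        raise ValidationError("aberrant reference list is empty")
    best_id, best_ref = max(
        ((global_identity(consensus, ref.sequence), ref.id) for ref in aberrant_refs),
    )
    if best_id >= min_identity:
        return AberranceCall(True, "reference_match", best_ref, best_id, orf)
    if orf is None:
        orf = annotate_orf(consensus)
    if orf.premature_stop:
        return AberranceCall(True, "premature_stop", best_ref, best_id, orf)
    return AberranceCall(False, "productive", best_ref, best_id, orf)


def compare_to_strain(
    sample_constant: str,
    refs: list[ReferenceRecord],
    aa_offset: int = 0,
    sample_label: str = "query",
) -> list[StrainComparison]:
    """Rank strain constant-region references by nucleotide distance.

    Each reference is globally aligned to the sample constant region;
    substitution columns are reported 1-based, and amino-acid
    differences come from codon-aligned translation of the sample
    frame.  ``aa_offset`` shifts reported amino-acid positions into
    mature-chain numbering (pass the variable-domain length so that a
    CH3 exchange is reported at e.g. position 435 of the assembled
    leaderless heavy chain); nucleotide positions are shifted by
    ``3 * aa_offset`` accordingly.
    """
    candidates = [r for r in refs if r.category == "constant_region"]
    if not candidates:
        raise ValidationError("no constant_region references supplied")
    results = []
    for ref in candidates:
        if len(ref.sequence) < 50:
            raise ValidationError(f"reference {ref.id!r} shorter than 50 nt")
        results.append(_compare_pair(sample_constant, ref, aa_offset, sample_label))
    results.sort(key=lambda c: (len(c.nt_differences), c.strain_b_id))
    return results


def _compare_pair(sample: str, ref: ReferenceRecord, aa_offset: int, sample_label: str) -> StrainComparison:
    aln = align_global(sample, ref.sequence)
    s_row, r_row = str(aln[0]), str(aln[1])
    nt_diffs: list[tuple[int, str, str]] = []
    # substitutions in sample coordinates; per-codon ref projection for aa calls
    sample_pos = 0
    ref_base_at: dict[int, str] = {}
    for a, b in zip(s_row, r_row):
        if a != "-":
            if b != "-":
                ref_base_at[sample_pos] = b
                if a != b:
                    nt_diffs.append((sample_pos + 1 + 3 * aa_offset, a, b))
            sample_pos += 1
    aa_diffs: list[tuple[int, str, str]] = []
    flagged_codons = sorted({(pos - 1 - 3 * aa_offset) // 3 for pos, _, _ in nt_diffs})
    for codon_idx in flagged_codons:
        codon_s = sample[3 * codon_idx: 3 * codon_idx + 3]
        codon_r = "".join(ref_base_at.get(3 * codon_idx + k, "-") for k in range(3))
        if len(codon_s) < 3 or "-" in codon_r:
            continue
        aa_s = str(Seq(codon_s).translate())
        aa_r = str(Seq(codon_r).translate())
        if aa_s != aa_r:
            aa_diffs.append((codon_idx + 1 + aa_offset, aa_s, aa_r))
    return StrainComparison(
        strain_a_id=sample_label,
        strain_b_id=ref.id,
        nt_differences=nt_diffs,
        aa_differences=aa_diffs,
    )
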