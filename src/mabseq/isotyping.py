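"""DNA-level mouse IgG subclass calling and primer binding-site audit.

The CH1 exon of the mouse IgG heavy chain is highly conserved within a
subclass but carries short subclass-specific stretches.  Because the
variable-region RT-PCR amplicon reaches into CH1, those motifs ride
along with every heavy-chain consensus and allow the subclass (IgG1,
IgG2a, IgG2b, IgG2c, IgG3) to be called at the DNA level -- which
matters for IgG2c, a subclass that protein-level lateral-flow kits
often cannot resolve.  Light-chain class (kappa/lambda) is called by
constant-region identity.

Motif matching is exact on both strands: the motifs live in conserved
sequence and the query is a consensus, not a raw read.  The primer
audit is an ungapped minimum-Hamming scan, matching how annealing
mismatches are counted positionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import hamming, overlap_identity, revcomp
from .errors import ValidationError
from .io import PrimerRecord, ReferenceRecord


@dataclass
class MotifSet:
    """Per-subclass discriminative k-mers derived from CH1 references."""

    motifs: dict[str, list[tuple[str, int]]]
    alignment_length: int

    def all_motifs(self):
        for subclass, pairs in self.motifs.items():
            for motif, offset in pairs:
                yield subclass, motif, offset


@dataclass
class IsotypeCall:
    subclass: str
    light_chain: str
    evidence: list[tuple[str, str, int, str]] = field(default_factory=list)
    light_identity_pct: float | None = None
    lambda_low_confidence: bool = False


@dataclass
class PrimerSiteReport:
    """Best ungapped placement of one primer on one reference."""

    primer: PrimerRecord
    reference_id: str
    mismatches: int
    mismatch_positions: list[int]
    orientation: str
    offset: int


def derive_motifs(ch1_refs: list[ReferenceRecord], k_range: tuple[int, int] = (8, 20)) -> MotifSet:
    """Extract minimal subclass-unique windows from CH1 references.

    A window is *unique* when it occurs in its own subclass reference
    and in no other reference of the set (either strand).  All unique
    windows of minimal length are reported: a window containing a
    shorter reported window is suppressed.  A subclass without any
    unique window in ``k_range`` raises, naming the subclass -- which
    also covers duplicated reference sequences.
    """
    if not ch1_refs:
        raise ValidationError("no CH1 references")
    k_lo, k_hi = k_range
    by_subclass = {r.subclass_or_strain: r for r in ch1_refs}
    if len(by_subclass) != len(ch1_refs):
        raise ValidationError("duplicate subclass labels in CH1 reference set")

    motifs: dict[str, list[tuple[str, int]]] = {}
    for subclass, ref in by_subclass.items():
        others = [o for o in ch1_refs if o is not ref]
        haystacks = [o.sequence for o in others] + [revcomp(o.sequence) for o in others]
        unique: list[tuple[str, int]] = []
        for k in range(k_lo, k_hi + 1):
            for off in range(len(ref.sequence) - k + 1):
                window = ref.sequence[off:off + k]
                if any(window in h for h in haystacks):
                    continue
                if any(m in window for m, _ in unique):
                    continue  # a shorter unique window is contained in it
                unique.append((window, off))
        if not unique:
            raise ValidationError(
                f"subclass {subclass!r} has no unique window of length {k_lo}-{k_hi}"
            )
        motifs[subclass] = unique
    return MotifSet(motifs=motifs, alignment_length=max(len(r.sequence) for r in ch1_refs))


def call_isotype(
    consensus: str,
    motifs: MotifSet,
    light_refs: list[ReferenceRecord],
    light_identity_min: float = 0.90,
    primers: list[PrimerRecord] | None = None,
) -> IsotypeCall:
    """Call IgG subclass by exact motif scan and light class by identity.

    The subclass is returned only when exactly one subclass has motif
    support ("ambiguous" is a value, not an error).  Light-chain class
    is the best constant-region identity above ``light_identity_min``;
    a lambda call is flagged low-confidence when a supplied lambda
    primer shows more than one mismatch against the chosen reference,
    since lambda amplification is known to be less efficient.
    """
    rc = revcomp(consensus)
    evidence: list[tuple[str, str, int, str]] = []
    supported = set()
    for subclass, motif, _ in motifs.all_motifs():
        pos = consensus.find(motif)
        if pos >= 0:
            evidence.append((subclass, motif, pos, "+"))
            supported.add(subclass)
            continue
        pos = rc.find(motif)
        if pos >= 0:
            evidence.append((subclass, motif, pos, "-"))
            supported.add(subclass)
    subclass = next(iter(supported)) if len(supported) == 1 else "ambiguous"

    light_chain = "none"
    light_identity = None
    low_confidence = False
    chosen_ref = None
    candidates = [r for r in light_refs if r.category == "constant_region"]
    if candidates:
        scored = [(max(overlap_identity(consensus, r.sequence),
                       overlap_identity(rc, r.sequence)), r) for r in candidates]
        best_score, best_ref = max(scored, key=lambda t: (t[0], t[1].id))
        if best_score >= light_identity_min:
            light_chain = _light_class(best_ref)
            light_identity = 100.0 * best_score
            chosen_ref = best_ref
    if light_chain == "lambda" and primers and chosen_ref is not None:
        lambda_primers = [p for p in primers if "IGL" in p.name.upper() and p.role in ("RT", "PCR")]
        for p in lambda_primers:
            report = scan_primer_sites(p, [chosen_ref])[0]
            if report.mismatches > 1:
                low_confidence = True
    return IsotypeCall(
        subclass=subclass,
        light_chain=light_chain,
        evidence=sorted(evidence),
        light_identity_pct=light_identity,
        lambda_low_confidence=low_confidence,
    )


def _light_class(ref: ReferenceRecord) -> str:
    label = (ref.subclass_or_strain or ref.id).lower()
    if label.startswith(("igk", "kappa")) or "kappa" in label:
        return "kappa"
    return "lambda"


def scan_primer_sites(primer: PrimerRecord, refs: list[ReferenceRecord]) -> list[PrimerSiteReport]:
    """Slide a primer ungapped across each reference, minimising mismatches.

    Both orientations are scanned; the better one is kept (ties go to
    the antisense placement for RT/PCR primers, which anneal to the
    sense strand).  Mismatch positions are 1-based within the primer,
    counted from its 5' end.
    """
    reports = []
    for ref in refs:
        if len(primer.sequence) > len(ref.sequence):
            raise ValidationError(
                f"primer {primer.name!r} longer than reference {ref.id!r}"
            )
        best = None  # (mismatches, orient_rank, offset, orientation, positions)
        prefer_antisense = primer.role in ("RT", "PCR")
        for orientation in ("sense", "antisense"):
            probe = primer.sequence if orientation == "sense" else revcomp(primer.sequence)
            rank = (orientation == "antisense") != prefer_antisense
            for off in range(len(ref.sequence) - len(probe) + 1):
                window = ref.sequence[off:off + len(probe)]
                mm = hamming(probe, window)
                if best is None or (mm, rank, off) < (best[0], best[1], best[2]):
                    positions = [
                        (j + 1) if orientation == "sense" else (len(probe) - j)
                        for j in range(len(probe))
                        if probe[j] != window[j]
                    ]
                    best = (mm, rank, off, orientation, sorted(positions))
        mm, _, off, orientation, positions = best
        reports.append(
            PrimerSiteReport(
                primer=primer,
                reference_id=ref.id,
                mismatches=mm,
                mismatch_positions=positions,
                orientation=orientation,
                offset=off,
            )
        )
    return reports
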