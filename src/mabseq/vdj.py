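"""CDR3 junction detection and germline V/(D)/J assignment.

The CDR3 is defined IMGT-style: the codons strictly between the
conserved second cysteine at the end of framework 3 and the conserved
J-segment anchor (Trp for heavy chains, Phe/Trp for light chains).
Rather than motif regexes -- which break on somatically mutated
frameworks -- the anchors are located in the best-matching germline V
and J references and projected onto the query through the alignment
that the germline assignment already computed.

Germline assignment is plain global-alignment percent identity over
the aligned segment span.  It is intentionally simpler than IgBLAST's
composite scoring, so identities are comparable but not bit-identical
to an IgBLAST report; references tied within 0.1 percentage points of
the best are all returned, mirroring how database searches report
co-best alleles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .align import align_infix, infix_identity, project_position, revcomp
from .errors import JunctionError, ValidationError
from .io import ReferenceRecord


@dataclass
class GermlineAssignment:
    """Ranked germline calls for one segment category."""

    calls: list[str]
    top_identity_pct: float
    identities: dict[str, float] = field(default_factory=dict)


@dataclass
class ChainAnnotation:
    """Summary annotation of one variable-region consensus."""

    chain_type: str
    v_call: str
    j_call: str
    cdr3_nt: str
    cdr3_aa: str
    cdr3_span: tuple[int, int]
    total_identity_pct: float
    productive: bool
    d_call: str = ""
    orientation: str = "+"


def assign_germline(
    consensus: str,
    refs: list[ReferenceRecord],
    tie_margin_pct: float = 0.1,
    auto_orient: bool = True,
) -> GermlineAssignment:
    """Percent identity of the consensus against a germline reference set.

    Each reference is infix-aligned into the consensus (both strands
    when ``auto_orient``); identity is matches over aligned reference
    columns, in percent.  All references within ``tie_margin_pct`` of
    the best are reported as co-best calls.
    """
    if not refs:
        raise ValidationError("empty germline reference set")
    identities: dict[str, float] = {}
    for ref in refs:
        ident, _ = infix_identity(consensus, ref.sequence)
        if auto_orient:
            ident_rc, _ = infix_identity(revcomp(consensus), ref.sequence)
            ident = max(ident, ident_rc)
        identities[ref.id] = 100.0 * ident
    top = max(identities.values())
    calls = sorted((r.id for r in refs if identities[r.id] >= top - tie_margin_pct))
    return GermlineAssignment(calls=calls, top_identity_pct=top, identities=identities)


def find_cdr3(
    consensus: str,
    chain_type: str,
    v_refs: list[ReferenceRecord],
    j_refs: list[ReferenceRecord],
) -> tuple[str, str, tuple[int, int]]:
    """Locate the CDR3 by V/J anchor projection.

    Returns ``(cdr3_nt, cdr3_aa, span)`` with a half-open 0-based
    nucleotide span on the (possibly re-oriented) consensus.  Raises
    :class:`JunctionError` when either anchor cannot be located or the
    projected anchors do not bound a junction.
    """
    if not v_refs or not j_refs:
        raise ValidationError("V and J reference sets must be non-empty")
    consensus = _orient(consensus, v_refs)

    best_v = max(v_refs, key=lambda r: infix_identity(consensus, r.sequence)[0])
    cys_end = _v_anchor_end(best_v)
    v_aln = align_infix(consensus, best_v.sequence)
    q_cys_end = project_position(v_aln, cys_end - 1) + 1

    best_j = max(j_refs, key=lambda r: infix_identity(consensus, r.sequence)[0])
    j_anchor = _j_anchor_start(best_j, chain_type)
    j_aln = align_infix(consensus, best_j.sequence)
    q_j_start = project_position(j_aln, j_anchor)

    if q_j_start <= q_cys_end:
        raise JunctionError(
            "junction not resolvable: J anchor does not lie downstream of the V cysteine",
            partial={"v_ref": best_v.id, "j_ref": best_j.id,
                     "cys_end": q_cys_end, "j_start": q_j_start},
        )
    cdr3_nt = consensus[q_cys_end:q_j_start]
    cdr3_aa = str(Seq(cdr3_nt).translate()) if len(cdr3_nt) % 3 == 0 else ""
    return cdr3_nt, cdr3_aa, (q_cys_end, q_j_start)


def annotate_chain(
    consensus: str,
    chain_type: str,
    v_refs: list[ReferenceRecord],
    j_refs: list[ReferenceRecord],
    d_refs: list[ReferenceRecord] | None = None,
) -> ChainAnnotation:
    """Full annotation: germline calls plus CDR3 junction."""
    oriented = _orient(consensus, v_refs)
    orientation = "+" if oriented == consensus else "-"
    v = assign_germline(oriented, v_refs, auto_orient=False)
    j = assign_germline(oriented, j_refs, auto_orient=False)
    cdr3_nt, cdr3_aa, span = find_cdr3(oriented, chain_type, v_refs, j_refs)
    d_call = ""
    if chain_type == "heavy" and d_refs:
        d = assign_germline(oriented, d_refs, auto_orient=False)
        d_call = ",".join(d.calls)
    productive = len(cdr3_nt) % 3 == 0 and bool(cdr3_aa) and "*" not in cdr3_aa
    return ChainAnnotation(
        chain_type=chain_type,
        v_call=",".join(v.calls),
        j_call=",".join(j.calls),
        d_call=d_call,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        cdr3_span=span,
        total_identity_pct=v.top_identity_pct,
        productive=productive,
        orientation=orientation,
    )


def _orient(consensus: str, v_refs: list[ReferenceRecord]) -> str:
    """Return the strand of the consensus that best matches the V set."""
    fwd = max(infix_identity(consensus, r.sequence)[0] for r in v_refs)
    rc = revcomp(consensus)
    rev = max(infix_identity(rc, r.sequence)[0] for r in v_refs)
    return rc if rev > fwd else consensus


def _v_anchor_end(v_ref: ReferenceRecord) -> int:
    """End (exclusive) of the last in-frame Cys codon of a germline V."""
    positions = [p for p in range(0, len(v_ref.sequence) - 2, 3)
                 if v_ref.sequence[p:p + 3] in ("TGT", "TGC")]
    if not positions:
        raise JunctionError(f"no in-frame cysteine anchor in V reference {v_ref.id!r}")
    return positions[-1] + 3

_J_MOTIF = {"heavy": r"W(?=G.G)", "kappa": r"[FW](?=G.G)", "lambda": r"[FW](?=G.G)"}


def _j_anchor_start(j_ref: ReferenceRecord, chain_type: str) -> int:
    """Start of the conserved J anchor codon ([FW]-G-x-G motif)."""
    pattern = _J_MOTIF.get(chain_type, r"[FW](?=G.G)")
    for frame in range(3):
        coding = j_ref.sequence[frame:]
        coding = coding[: len(coding) - len(coding) % 3]
        aa = str(Seq(coding).translate())
        m = re.search(pattern, aa)
        if m:
            return frame + 3 * m.start()
    raise JunctionError(f"no [FW]GxG anchor motif in J reference {j_ref.id!r}")
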