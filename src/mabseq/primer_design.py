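"""CDR3-anchored primer design and 3'RACE amplicon prediction.

For constant-region sequencing the forward primer is anchored on the
clone-specific CDR3 junction: its 5' end is pinned to the CDR3 start
(preserving junction specificity) and only the 3' end is trimmed or
extended into FR4 to satisfy the melting-temperature window.  The
reverse boundary of the in-silico amplicon is set by the oligo-dT
anchor primer at the 5' end of the poly-A tract.

Melting temperatures use nearest-neighbour thermodynamics
(:func:`Bio.SeqUtils.MeltingTemp.Tm_NN`) with 50 mM Na+ and 250 nM
primer -- documented constants, configurable per call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt
from Bio.SeqUtils import gc_fraction

from .errors import ConstraintError, ValidationError
from .io import PrimerRecord
from .vdj import ChainAnnotation

TM_DEFAULTS = {"Na": 50.0, "dnac1": 250.0, "dnac2": 25.0}


@dataclass
class PrimerSpec:
    """A designed primer with its thermodynamic summary."""

    name: str
    sequence: str
    tm_celsius: float
    gc_fraction: float
    anchor: str

    def __post_init__(self):
        if not 15 <= len(self.sequence) <= 40:
            raise ValidationError(
                f"primer {self.name!r}: length {len(self.sequence)} outside 15-40"
            )


@dataclass
class AmpliconPrediction:
    forward: PrimerSpec
    reverse: PrimerSpec
    product_length_nt: int
    covers: list[str] = field(default_factory=list)
    forward_start: int = 0
    reverse_end: int = 0


def melting_temperature(sequence: str, **params) -> float:
    """Nearest-neighbour melting temperature in Celsius."""
    if len(sequence) < 8:
        raise ValidationError("Tm model needs at least 8 nt")
    if not re.fullmatch(r"[ACGT]+", sequence):
        raise ValidationError("Tm model accepts only A/C/G/T (no N)")
    kwargs = {**TM_DEFAULTS, **params}
    return float(_mt.Tm_NN(sequence, **kwargs))


def design_cdr3_primer(
    annotation: ChainAnnotation,
    template: str,
    tm_window: tuple[float, float] = (55.0, 65.0),
    length_window: tuple[int, int] = (15, 40),
    name: str | None = None,
) -> PrimerSpec:
    """Design the forward primer anchored on the CDR3 junction.

    Candidates share the CDR3 start as 5' end and vary only in 3'
    extent.  Among candidates inside the Tm window the one closest to
    the native CDR3 length is chosen (full-junction coverage preferred);
    the winner must occur exactly once in the template.
    """
    cdr3 = annotation.cdr3_nt
    if not cdr3:
        raise ValidationError("annotation has no CDR3 sequence")
    occurrences = template.count(cdr3)
    if occurrences == 0:
        raise ValidationError("CDR3 not found in template")
    if occurrences > 1:
        raise ConstraintError("non-unique anchor: CDR3 occurs more than once in template")
    start = template.index(cdr3)

    lo, hi = length_window
    tm_lo, tm_hi = tm_window
    mid = (tm_lo + tm_hi) / 2
    candidates = []
    for length in range(lo, hi + 1):
        if start + length > len(template):
            break
        seq = template[start:start + length]
        if "N" in seq:
            continue
        tm = melting_temperature(seq)
        candidates.append((length, seq, tm))
    feasible = [(L, s, tm) for L, s, tm in candidates if tm_lo <= tm <= tm_hi]
    feasible.sort(key=lambda t: (t[0] < len(cdr3), abs(t[0] - len(cdr3)), abs(t[2] - mid)))
    for length, seq, tm in feasible:
        if template.count(seq) == 1:
            return PrimerSpec(
                name=name or f"{annotation.chain_type}_cdr3_fwd",
                sequence=seq,
                tm_celsius=tm,
                gc_fraction=gc_fraction(seq),
                anchor=f"CDR3, nt {start + 1}-{start + length} of template",
            )
    achieved = ", ".join(f"{L}nt:{tm:.1f}C" for L, _, tm in candidates[:5])
    raise ConstraintError(
        f"no primer satisfies Tm {tm_lo}-{tm_hi} C within length {lo}-{hi} "
        f"(candidate Tm values start at {achieved})"
    )


def find_polya(template: str, min_run: int = 10, search_window: int = 50) -> int:
    """5' end of the poly-A tract: first run of >=``min_run`` A within the final window."""
    tail_start = max(0, len(template) - search_window)
    m = re.search("A{%d,}" % min_run, template[tail_start:])
    if not m:
        raise ValidationError(
            f"not a 3'RACE template: no run of >={min_run} A in the final {search_window} nt"
        )
    return tail_start + m.start()


def predict_amplicon(
    forward: PrimerSpec,
    template_mrna: str,
    anchor_primer: PrimerRecord,
    regions: dict[str, tuple[int, int]] | None = None,
) -> AmpliconPrediction:
    """Predict the RT-3'RACE product of a CDR3 forward primer.

    The product runs from the forward binding site to the 5' end of the
    poly-A tract, plus the full length of the oligo-dT anchor primer
    that forms the amplicon's 3' terminus.  ``covers`` lists the
    annotated template regions intersected by the product.
    """
    occurrences = template_mrna.count(forward.sequence)
    if occurrences == 0:
        raise ValidationError(f"forward primer {forward.name!r} does not bind the template")
    if occurrences > 1:
        raise ConstraintError(f"forward primer {forward.name!r} binds the template more than once")
    start = template_mrna.index(forward.sequence)
    polya_start = find_polya(template_mrna)
    product_length = polya_start - start + len(anchor_primer.sequence)

    reverse = PrimerSpec(
        name=anchor_primer.name,
        sequence=anchor_primer.sequence[:40] if len(anchor_primer.sequence) > 40 else anchor_primer.sequence,
        tm_celsius=float("nan"),
        gc_fraction=gc_fraction(anchor_primer.sequence),
        anchor="poly-A tract (oligo-dT anchor)",
    )
    covers = []
    if regions:
        for label, (lo, hi) in regions.items():
            if lo < polya_start and hi > start:
                covers.append(label)
    return AmpliconPrediction(
        forward=forward,
        reverse=reverse,
        product_length_nt=product_length,
        covers=covers,
        forward_start=start,
        reverse_end=polya_start,
    )
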