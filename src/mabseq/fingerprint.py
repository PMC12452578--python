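"""Peptide-mass-fingerprint verification of antibody CDRs.

The assembled heavy and light chain proteins are digested in silico --
with trypsin (cleavage after Lys/Arg except before Pro) or with dilute
sulfuric acid (aspartate-selective hydrolysis cleaving on both sides of
Asp, which is intrinsically partial, hence a generous missed-site
allowance) -- and the theoretical monoisotopic [M+H]+ masses are
matched against a measured MALDI-TOF peak list within a ppm tolerance.
Matched peptides give sequence coverage and a per-CDR verdict: a CDR
counts as assigned only when one matched peptide fully contains its
span.

Masses are singly protonated monoisotopic values (reflector-mode
MALDI), computed with :mod:`pyteomics.mass`; cysteine is unmodified by
default (no alkylation step), with carbamidomethyl available as a fixed
modification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

from .errors import ValidationError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
WATER_MONO = 18.010565
PROTON_MONO = 1.007276
CARBAMIDOMETHYL = 57.021464

DEFAULT_MAX_MISSED = {"trypsin": 2, "acid": 5}


@dataclass
class TheoreticalPeptide:
    """One in-silico cleavage fragment with its [M+H]+ mass."""

    sequence: str
    start: int  # 1-based inclusive in the parent chain
    end: int
    chain: str
    missed_sites: int
    mh_mono: float
    cleavage_mode: str


@dataclass
class PeptideMatch:
    mz: float
    peptide: TheoreticalPeptide
    error_ppm: float


@dataclass
class FingerprintResult:
    matches: list[PeptideMatch]
    coverage_fraction: float
    cdr_assignments: dict[str, tuple[bool, list[TheoreticalPeptide]]] = field(default_factory=dict)


@dataclass
class CdrSpan:
    """A CDR span, 1-based inclusive, within one chain."""

    label: str
    chain: str
    start: int
    end: int


def _check_protein(protein: str) -> None:
    if not protein:
        raise ValidationError("empty protein sequence")
    for i, c in enumerate(protein):
        if c not in STANDARD_AA:
            raise ValidationError(f"nonstandard residue {c!r} at position {i + 1}")


def cleavage_sites(protein: str, mode: str) -> list[int]:
    """Internal cut positions (index i = bond between residues i and i+1).

    trypsin: after K or R unless the next residue is P;
    acid: on both sides of D (Asp-X and X-Asp bonds).
    """
    n = len(protein)
    if mode == "trypsin":
        return [i for i in range(1, n) if protein[i - 1] in "KR" and protein[i] != "P"]
    if mode == "acid":
        sites = {i for i in range(1, n) if protein[i - 1] == "D" or protein[i] == "D"}
        return sorted(sites)
    raise ValidationError(f"unknown cleavage mode {mode!r}")


def digest(
    protein: str,
    mode: str,
    max_missed: int | None = None,
    length_range: tuple[int, int] = (4, 40),
    chain: str = "heavy",
    cys_fixed_mod: str = "none",
) -> list[TheoreticalPeptide]:
    """Enumerate cleavage fragments with up to ``max_missed`` internal sites.

    The 4-40 residue length filter (reflector mass window, matrix-region
    exclusion) is applied after enumeration.  Defaults for ``max_missed``
    are 2 for trypsin and 5 for acid, reflecting the partial nature of
    dilute-acid hydrolysis.
    """
    _check_protein(protein)
    if max_missed is None:
        max_missed = DEFAULT_MAX_MISSED.get(mode, 2)
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")
    cuts = [0] + cleavage_sites(protein, mode) + [len(protein)]
    lo, hi = length_range
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            frag = protein[cuts[i]:cuts[j]]
            if not lo <= len(frag) <= hi:
                continue
            peptides.append(
                TheoreticalPeptide(
                    sequence=frag,
                    start=cuts[i] + 1,
                    end=cuts[j],
                    chain=chain,
                    missed_sites=j - i - 1,
                    mh_mono=peptide_mass(frag, cys_fixed_mod=cys_fixed_mod),
                    cleavage_mode=mode,
                )
            )
    return peptides


def peptide_mass(sequence: str, cys_fixed_mod: str = "none") -> float:
    """Monoisotopic [M+H]+ mass: residue masses + water + proton."""
    _check_protein(sequence)
    if cys_fixed_mod not in ("none", "carbamidomethyl"):
        raise ValidationError(f"unknown fixed modification {cys_fixed_mod!r}")
    mh = float(_pmass.calculate_mass(sequence=sequence, charge=1))
    if cys_fixed_mod == "carbamidomethyl":
        mh += CARBAMIDOMETHYL * sequence.count("C")
    return mh


def match_peaks(
    peaks,
    theoreticals: list[TheoreticalPeptide],
    tol_ppm: float = 100.0,
    cdr_spans: list[CdrSpan] | None = None,
    chain_lengths: dict[str, int] | None = None,
) -> FingerprintResult:
    """Match measured peaks to theoretical peptides within a ppm tolerance.

    Each peak is assigned to the theoretical peptide minimising
    ``|error_ppm|`` (a peak matches at most one peptide; a peptide may
    explain several peaks).  Coverage is the union of matched residue
    spans over the concatenated chains; totals come from
    ``chain_lengths`` when given, otherwise from the largest ``end``
    seen per chain among the theoreticals.
    """
    if tol_ppm <= 0:
        raise ValidationError("tol_ppm must be positive")
    matches: list[PeptideMatch] = []
    for mz, _intensity in getattr(peaks, "peaks", peaks):
        best = None
        for pep in theoreticals:
            err = (mz - pep.mh_mono) / pep.mh_mono * 1e6
            if abs(err) <= tol_ppm and (best is None or abs(err) < abs(best.error_ppm)):
                best = PeptideMatch(mz=mz, peptide=pep, error_ppm=err)
        if best is not None:
            matches.append(best)

    covered: dict[str, set[int]] = {}
    for m in matches:
        covered.setdefault(m.peptide.chain, set()).update(
            range(m.peptide.start, m.peptide.end + 1)
        )
    if chain_lengths is None:
        chain_lengths = {}
        for pep in theoreticals:
            chain_lengths[pep.chain] = max(chain_lengths.get(pep.chain, 0), pep.end)
    total = sum(chain_lengths.values())
    coverage = sum(len(covered.get(c, ())) for c in chain_lengths) / total if total else 0.0

    assignments: dict[str, tuple[bool, list[TheoreticalPeptide]]] = {}
    if cdr_spans:
        matched_peps = {id(m.peptide): m.peptide for m in matches}
        for span in cdr_spans:
            supporting = [
                p for p in matched_peps.values()
                if p.chain == span.chain and p.start <= span.start and span.end <= p.end
            ]
            assignments[span.label] = (bool(supporting), supporting)
    return FingerprintResult(matches=matches, coverage_fraction=coverage, cdr_assignments=assignments)


def cdr_spans(
    chain: str,
    chain_protein: str,
    cdr3_aa: str,
    cdr1: tuple[int, int] | None = None,
    cdr2: tuple[int, int] | None = None,
    prefix: str | None = None,
) -> list[CdrSpan]:
    """Normalise per-chain CDR spans (1-based inclusive).

    CDR3 is located automatically from the annotated junction peptide;
    CDR1/CDR2 are user-supplied spans (they are protein-level inputs,
    not called from the DNA).  Overlapping or out-of-range spans raise.
    """
    prefix = prefix or ("H" if chain == "heavy" else "L")
    if not cdr3_aa:
        raise ValidationError("annotation has no CDR3 peptide")
    pos = chain_protein.find(cdr3_aa)
    if pos < 0:
        raise ValidationError("CDR3 peptide not found in chain protein")
    spans = []
    for label, span in (("CDR1", cdr1), ("CDR2", cdr2)):
        if span is None:
            continue
        start, end = span
        if end < start:
            raise ValidationError(f"{label}: span end < start")
        if start < 1 or end > len(chain_protein):
            raise ValidationError(f"{label}: span outside chain (length {len(chain_protein)})")
        spans.append(CdrSpan(label=f"{prefix}-{label}", chain=chain, start=start, end=end))
    spans.append(CdrSpan(label=f"{prefix}-CDR3", chain=chain, start=pos + 1, end=pos + len(cdr3_aa)))
    spans.sort(key=lambda s: s.start)
    for a, b in zip(spans, spans[1:]):
        if b.start <= a.end:
            raise ValidationError(f"overlapping CDR spans {a.label} and {b.label}")
    return spans
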