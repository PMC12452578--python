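"""Shared pairwise-alignment helpers.

All sequence comparison in the package goes through two aligner
configurations built on :class:`Bio.Align.PairwiseAligner`:

* a plain global (Needleman-Wunsch) aligner with match +1, mismatch -1,
  gap open -2, gap extend -1, used when both sequences cover the same
  amplicon (clone reads, strain references);
* an *infix* variant of the same scoring in which end gaps on the longer
  ("target") sequence are free, used to place a short reference segment
  (germline V/J, constant-region stub) inside a longer consensus.

Identity is always matches / alignment columns over the compared span.
"""

from __future__ import annotations

import warnings

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

STOP_CODONS = {"TAA", "TAG", "TGA"}

# IUPAC code for each set of tied bases (majority-vote tie rule)
IUPAC_FROM_SET = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _base_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -1.0
    return a


def global_aligner() -> Align.PairwiseAligner:
    """Global aligner for sequences expected to cover the same region."""
    return _base_aligner()


def infix_aligner() -> Align.PairwiseAligner:
    """Aligner that embeds the (short) query inside the (long) target.

    End gaps in the query row -- i.e. target overhangs -- are free, so
    the query is pinned to its best matching window without paying for
    the flanks.
    """
    a = _base_aligner()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a.end_deletion_score = 0.0
    return a


def align_global(a: str, b: str):
    """Best global alignment of two sequences."""
    return global_aligner().align(a, b)[0]


def global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the best global alignment."""
    aln = align_global(a, b)
    s1, s2 = str(aln[0]), str(aln[1])
    return sum(x == y for x, y in zip(s1, s2)) / len(s1)


def align_infix(target: str, query: str):
    """Best infix alignment of ``query`` within ``target``."""
    return infix_aligner().align(target, query)[0]


def infix_identity(target: str, query: str) -> tuple[float, "Align.Alignment"]:
    """Identity of ``query`` over its aligned span within ``target``.

    Columns where the query row carries an end gap (the unaligned target
    flanks) are excluded; internal gaps count as mismatches.
    """
    aln = align_infix(target, query)
    s1, s2 = str(aln[0]), str(aln[1])
    lo = len(s2) - len(s2.lstrip("-"))
    hi = len(s2.rstrip("-"))
    if hi <= lo:
        return 0.0, aln
    matches = sum(s1[i] == s2[i] for i in range(lo, hi))
    return matches / (hi - lo), aln


def overlap_identity(a: str, b: str, min_overlap: int = 60) -> float:
    """Identity over the best overlap of two sequences.

    End gaps are free on both sequences, so a truncated amplicon can be
    scored against a full-length reference over the region they share.
    Overlaps shorter than ``min_overlap`` columns score 0.
    """
    aligner = _base_aligner()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aligner.end_deletion_score = 0.0
        aligner.end_insertion_score = 0.0
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    lo = max(len(s1) - len(s1.lstrip("-")), len(s2) - len(s2.lstrip("-")))
    hi = min(len(s1.rstrip("-")), len(s2.rstrip("-")))
    if hi - lo < min_overlap:
        return 0.0
    matches = sum(s1[i] == s2[i] for i in range(lo, hi))
    return matches / (hi - lo)


def project_position(aln, query_pos: int) -> int:
    """Map a query coordinate onto the target through an alignment.

    For positions falling inside a query-side gap the start of the next
    aligned block is returned; positions past the last block map to the
    end of the final target block.
    """
    tblocks, qblocks = aln.aligned
    last_end = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if qs <= query_pos < qe:
            return ts + (query_pos - qs)
        if query_pos < qs:
            return ts
        last_end = te
    if last_end is None:
        raise ValueError("empty alignment; cannot project position")
    return last_end


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
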