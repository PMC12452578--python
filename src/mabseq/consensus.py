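"""Clustering of near-identical Sanger clone reads and consensus calling.

Clone reads of a single transcript differ only by sequencing error,
while a second transcript (e.g. the non-functional kappa chain carried
over from the myeloma fusion partner) diverges far beyond the error
rate.  Single-linkage clustering on pairwise global-alignment identity
therefore separates transcripts, and a column-wise majority vote over a
progressive alignment to the longest member gives one consensus per
cluster.

Majority-vote rules
-------------------
* strict majority base is emitted;
* exact ties are emitted as the IUPAC code covering the tied bases;
* columns where the gap is in strict majority are deleted;
* ``N`` (Sanger ambiguity) never wins a vote -- the most frequent
  concrete base is used instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import IUPAC_FROM_SET, align_global, global_identity
from .errors import ValidationError
from .io import NucleotideRead


@dataclass
class ReadCluster:
    """A cluster of near-identical reads with its consensus."""

    members: list[NucleotideRead]
    consensus: str = ""
    support: list[float] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


def cluster_reads(reads: list[NucleotideRead], identity_threshold: float = 0.99) -> list[ReadCluster]:
    """Single-linkage clustering on pairwise global-alignment identity.

    Every read ends up in exactly one cluster.  Clusters are ordered by
    size descending, ties broken by lexicographically smallest member
    id, so the result is invariant to input order.
    """
    if not reads:
        raise ValidationError("no reads to cluster")
    if not 0.5 < identity_threshold <= 1.0:
        raise ValidationError(f"identity threshold must be in (0.5, 1], got {identity_threshold}")

    order = sorted(range(len(reads)), key=lambda i: reads[i].id)
    parent = list(range(len(reads)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_idx in range(len(order)):
        for b_idx in range(a_idx + 1, len(order)):
            i, j = order[a_idx], order[b_idx]
            if find(i) == find(j):
                continue
            if global_identity(reads[i].sequence, reads[j].sequence) >= identity_threshold:
                parent[find(j)] = find(i)

    groups: dict[int, list[NucleotideRead]] = {}
    for i, read in enumerate(reads):
        groups.setdefault(find(i), []).append(read)

    clusters = []
    for members in groups.values():
        members = sorted(members, key=lambda r: r.id)
        consensus, support = call_consensus(members)
        clusters.append(ReadCluster(members=members, consensus=consensus, support=support))
    clusters.sort(key=lambda c: (-c.size, min(c.member_ids)))
    return clusters


def call_consensus(members: list[NucleotideRead]) -> tuple[str, list[float]]:
    """Column-wise majority-vote consensus of a cluster.

    Members are pairwise-aligned to the longest member (ties by id) --
    full multiple-alignment machinery is unnecessary for near-identical
    reads.  Insertions relative to that backbone are kept only when a
    strict majority of members carries an insertion at the same
    position.
    """
    if not members:
        raise ValidationError("empty cluster")
    if len(members) == 1:
        seq = members[0].sequence
        return seq, [1.0] * len(seq)

    backbone = min(members, key=lambda r: (-len(r.sequence), r.id))
    ref = backbone.sequence
    n = len(members)

    per_member_cols: list[list[str]] = []
    per_member_ins: list[dict[int, str]] = []
    for m in members:
        if m is backbone:
            per_member_cols.append(list(ref))
            per_member_ins.append({})
            continue
        cols, ins = _map_to_backbone(ref, m.sequence)
        per_member_cols.append(cols)
        per_member_ins.append(ins)

    out: list[str] = []
    support: list[float] = []
    for pos in range(len(ref) + 1):
        inserted = [ins.get(pos, "") for ins in per_member_ins]
        non_empty = [s for s in inserted if s]
        if 2 * len(non_empty) > n:
            best, count = _majority_string(non_empty)
            out.append(best)
            support.extend([count / n] * len(best))
        if pos < len(ref):
            base, frac = _vote([cols[pos] for cols in per_member_cols], n)
            if base:
                out.append(base)
                support.append(frac)
    return "".join(out), support


def _map_to_backbone(ref: str, member: str) -> tuple[list[str], dict[int, str]]:
    """Project a member sequence onto backbone coordinates.

    Returns one character per backbone position ('-' where the member is
    deleted) plus insertions keyed by the backbone position they precede.
    """
    aln = align_global(ref, member)
    tblocks, qblocks = aln.aligned
    cols = ["-"] * len(ref)
    ins: dict[int, str] = {}
    prev_q_end = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if qs > prev_q_end:
            ins[ts] = ins.get(ts, "") + member[prev_q_end:qs]
        for k in range(te - ts):
            cols[ts + k] = member[qs + k]
        prev_q_end = qe
    if prev_q_end < len(member):
        ins[len(ref)] = ins.get(len(ref), "") + member[prev_q_end:]
    return cols, ins


def _majority_string(strings: list[str]) -> tuple[str, int]:
    counts = Counter(strings)
    best_count = max(counts.values())
    best = min(s for s, c in counts.items() if c == best_count)
    return best, best_count


def _vote(chars: list[str], n: int) -> tuple[str, float]:
    """Majority vote for one column; empty string means column deleted."""
    counts = Counter(chars)
    if 2 * counts.get("-", 0) > n:
        return "", 0.0
    concrete = {b: c for b, c in counts.items() if b in "ACGT"}
    if not concrete:
        # all N (or N vs gap): fall back to N
        return ("N", counts.get("N", 0) / n) if counts.get("N") else ("", 0.0)
    best_count = max(concrete.values())
    tied = frozenset(b for b, c in concrete.items() if c == best_count)
    if len(tied) == 1:
        base = next(iter(tied))
    else:
        base = IUPAC_FROM_SET[tied]
    return base, best_count / n
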