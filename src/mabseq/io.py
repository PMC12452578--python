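"""Input/output layer and the shared sequence data model.

Reads and writes the plain-text formats the workflow consumes: FASTA
nucleotide files (Sanger clone reads, reference bundles), delimited
primer tables, and two-column MALDI peak lists.  FASTA handling is done
with :mod:`Bio.SeqIO`.

Conventions
-----------
* Read sequences are uppercased, ``U`` is mapped to ``T``, and only
  ``{A, C, G, T, N}`` is accepted -- ``N`` encodes Sanger base-calling
  ambiguity and is allowed in reads but never in curated references.
* The FASTA description after the first whitespace is stored but never
  interpreted, except that for reference bundles the first description
  token is taken as the subclass/strain label.
* Peak lists are two-column (m/z, intensity) text, comma- or
  whitespace-delimited, ``#`` starting a header/comment line.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

READ_ALPHABET = set("ACGTN")
REFERENCE_ALPHABET = set("ACGT")

CHAIN_HINTS = {"heavy", "kappa", "lambda", "unknown"}
REFERENCE_CATEGORIES = {
    "germline_V", "germline_D", "germline_J",
    "CH1_exon", "constant_region", "aberrant_kappa",
}
PRIMER_ROLES = {"RT", "PCR", "template_switch", "oligo_dT_anchor", "vdj_specific"}
CLEAVAGE_MODES = {"trypsin", "acid"}


@dataclass
class NucleotideRead:
    """A single Sanger clone read."""

    id: str
    sequence: str
    chain_hint: str = "unknown"
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"read {self.id!r}: empty sequence")
        if self.chain_hint not in CHAIN_HINTS:
            raise ValidationError(f"read {self.id!r}: unknown chain hint {self.chain_hint!r}")
        bad = next((i for i, c in enumerate(self.sequence) if c not in READ_ALPHABET), None)
        if bad is not None:
            raise ValidationError(
                f"read {self.id!r}: illegal character {self.sequence[bad]!r} at position {bad + 1}"
            )


@dataclass
class ReferenceRecord:
    """A curated reference sequence (germline segment, CH1 exon, ...)."""

    id: str
    sequence: str
    category: str
    subclass_or_strain: str | None = None
    description: str = ""

    def __post_init__(self):
        if self.category not in REFERENCE_CATEGORIES:
            raise ValidationError(f"reference {self.id!r}: unknown category {self.category!r}")
        if not self.sequence:
            raise ValidationError(f"reference {self.id!r}: empty sequence")
        bad = next((i for i, c in enumerate(self.sequence) if c not in REFERENCE_ALPHABET), None)
        if bad is not None:
            raise ValidationError(
                f"reference {self.id!r}: illegal character {self.sequence[bad]!r} "
                f"at position {bad + 1} (N is not allowed in curated references)"
            )
        if self.category == "CH1_exon" and not self.subclass_or_strain:
            raise ValidationError(f"reference {self.id!r}: CH1_exon records need a subclass label")
        if self.category == "constant_region" and not self.subclass_or_strain:
            raise ValidationError(f"reference {self.id!r}: constant_region records need a strain/class label")


@dataclass
class PeakList:
    """An ordered MALDI peak list (m/z ascending)."""

    peaks: list[tuple[float, float]]
    source_label: str = ""
    cleavage_mode: str = "trypsin"

    def __post_init__(self):
        if self.cleavage_mode not in CLEAVAGE_MODES:
            raise ValidationError(f"unknown cleavage mode {self.cleavage_mode!r}")
        prev = 0.0
        for mz, intensity in self.peaks:
            if mz <= 0:
                raise ValidationError(f"peak m/z must be positive, got {mz}")
            if intensity < 0:
                raise ValidationError(f"peak intensity must be >= 0, got {intensity}")
            if mz <= prev:
                raise ValidationError("peak m/z values must be strictly increasing")
            prev = mz

    @property
    def mz(self):
        return [p[0] for p in self.peaks]


@dataclass
class PrimerRecord:
    """An oligonucleotide with its role in the workflow (5'->3')."""

    name: str
    sequence: str
    role: str

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"primer {self.name!r}: empty sequence")
        if self.role not in PRIMER_ROLES:
            raise ValidationError(
                f"primer {self.name!r}: unknown role {self.role!r} (expected one of {sorted(PRIMER_ROLES)})"
            )


def _normalise(seq: str, label: str) -> str:
    seq = seq.upper().replace("U", "T")
    for i, c in enumerate(seq):
        if c not in READ_ALPHABET:
            raise ParseError(f"record {label!r}: illegal character {c!r} at position {i + 1}")
    return seq


def read_fasta(path, chain_hint: str = "unknown") -> list[NucleotideRead]:
    """Read a FASTA file of nucleotide reads.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``; anything
    outside ``{A, C, G, T, N}`` raises :class:`ParseError` naming the
    record and 1-based position.  An empty file raises ``"no records"``.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            NucleotideRead(
                id=rec.id,
                sequence=_normalise(str(rec.seq), rec.id),
                chain_hint=chain_hint,
                description=desc,
            )
        )
    if not records:
        raise ParseError(f"no records in {path}")
    return records


def write_fasta(records: Iterable, path, wrap: int = 60) -> None:
    """Write reads/references to FASTA (sequence content round-trips)."""
    seqrecords = []
    for r in records:
        desc = getattr(r, "description", "") or ""
        seqrecords.append(SeqRecord(Seq(r.sequence), id=r.id if hasattr(r, "id") else r.name, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqrecords)


def read_reference_fasta(path, category: str) -> list[ReferenceRecord]:
    """Read a reference bundle; first description token = subclass/strain."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        label = desc.split()[0] if desc else None
        records.append(
            ReferenceRecord(
                id=rec.id,
                sequence=str(rec.seq).upper().replace("U", "T"),
                category=category,
                subclass_or_strain=label,
                description=desc,
            )
        )
    if not records:
        raise ParseError(f"no records in {path}")
    return records


def read_peaklist(path, mode: str) -> PeakList:
    """Read a two-column (m/z, intensity) text peak list.

    Duplicate m/z values are merged by intensity sum and the list is
    returned sorted ascending, which makes the reader idempotent under
    re-serialisation.
    """
    path = Path(path)
    merged: dict[float, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two columns")
            try:
                mz, intensity = float(fields[0]), float(fields[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric field") from None
            if mz <= 0:
                raise ValidationError(f"{path}: line {lineno}: m/z must be positive")
            merged[mz] = merged.get(mz, 0.0) + intensity
    peaks = sorted(merged.items())
    return PeakList(peaks=[(m, i) for m, i in peaks], source_label=path.name, cleavage_mode=mode)


def write_peaklist(peaklist: PeakList, path) -> None:
    with open(path, "w") as fh:
        fh.write("# m/z\tintensity\n")
        for mz, intensity in peaklist.peaks:
            fh.write(f"{mz:.6f}\t{intensity:.3f}\n")


def read_primer_table(path) -> list[PrimerRecord]:
    """Read a CSV/TSV primer table with columns name, sequence, role.

    A header row (first cell ``name``, case-insensitive) is skipped.
    An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        log.warning("primer table %s is empty", path)
        return []
    dialect = "excel-tab" if "\t" in text.splitlines()[0] else "excel"
    primers = []
    for rowno, row in enumerate(csv.reader(text.splitlines(), dialect), start=1):
        if not row or not "".join(row).strip():
            continue
        if rowno == 1 and row[0].strip().lower() == "name":
            continue
        if len(row) < 3:
            raise ParseError(f"{path}: row {rowno}: expected columns name, sequence, role")
        name, seq, role = (c.strip() for c in row[:3])
        try:
            primers.append(PrimerRecord(name=name, sequence=seq.upper().replace("U", "T"), role=role))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {rowno}: {exc}") from None
    return primers


def write_primer_table(primers: Sequence[PrimerRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "sequence", "role"])
        for p in primers:
            writer.writerow([p.name, p.sequence, p.role])
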