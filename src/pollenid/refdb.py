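"""Two-marker plant barcode reference database: data model, FASTA/TSV I/O,
and the rbcL pseudogene screen.

A reference database pairs a FASTA file of barcode sequences with a tab-separated
metadata table (columns ``record_id, species, marker, status, accession``).  Each
record carries one marker sequence — either the plastid *rbcL* gene or the
*trnH-psbA* intergenic spacer — for one species, together with its local
distribution status (common / rare / alien).  The FASTA id is the join key.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

MARKER_RBCL = "rbcL"
MARKER_TRNH = "trnH-psbA"
MARKERS = (MARKER_RBCL, MARKER_TRNH)

STATUSES = ("common", "rare", "alien")

#: IUPAC nucleotide codes accepted in reference and clone sequences.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

METADATA_COLUMNS = ["record_id", "species", "marker", "status", "accession"]

_PSEUDOGENE_FLAGS = ("pass", "internal_stop", "frameshift_indel")


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, U→T, and validate against the IUPAC DNA alphabet.

    Raises :class:`ValidationError` naming the 1-based position of the first
    illegal character.
    """
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValidationError(f"{context}: empty sequence")
    for i, ch in enumerate(s):
        if ch not in IUPAC_DNA:
            raise ValidationError(
                f"{context}: illegal character {ch!r} at position {i + 1}"
            )
    return s


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference barcode sequence with its taxonomy and status metadata."""

    record_id: str
    species: str
    marker: str
    status: str
    accession: str
    sequence: str

    @property
    def genus(self) -> str:
        return self.species.split()[0]

    def validate(self) -> "ReferenceRecord":
        if self.marker not in MARKERS:
            raise ValidationError(
                f"record {self.record_id!r}: marker {self.marker!r} "
                f"not in {MARKERS}"
            )
        if self.status not in STATUSES:
            raise ValidationError(
                f"record {self.record_id!r}: status {self.status!r} "
                f"not in {STATUSES}"
            )
        if not self.species.strip():
            raise ValidationError(f"record {self.record_id!r}: empty species name")
        seq = normalize_sequence(self.sequence, context=f"record {self.record_id!r}")
        if seq != self.sequence:
            return replace(self, sequence=seq)
        return self


@dataclass
class ReferenceDB:
    """A validated collection of :class:`ReferenceRecord`, unique per
    (species, marker), with per-marker lookup."""

    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = [r.validate() for r in self.records]
        self._index: dict[str, dict[str, ReferenceRecord]] = {m: {} for m in MARKERS}
        for rec in self.records:
            bucket = self._index[rec.marker]
            if rec.species in bucket:
                raise ValidationError(
                    f"duplicate (species, marker) pair: "
                    f"({rec.species!r}, {rec.marker!r})"
                )
            bucket[rec.species] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceDB):
            return NotImplemented
        return sorted(self.records, key=_sort_key) == sorted(other.records, key=_sort_key)

    def for_marker(self, marker: str) -> list[ReferenceRecord]:
        if marker not in MARKERS:
            raise ValidationError(f"unknown marker {marker!r}")
        return list(self._index[marker].values())

    def lookup(self, species: str, marker: str) -> ReferenceRecord | None:
        if marker not in MARKERS:
            raise ValidationError(f"unknown marker {marker!r}")
        return self._index[marker].get(species)

    @property
    def species(self) -> set[str]:
        return {r.species for r in self.records}


def _sort_key(rec: ReferenceRecord) -> tuple[str, str]:
    return (rec.species, rec.marker)


def read_reference(fasta_path: str | Path, metadata_path: str | Path) -> ReferenceDB:
    """Load a reference database from a FASTA file plus its metadata TSV.

    Every FASTA id must resolve to a metadata row; sequences are uppercased and
    U→T normalized. Missing metadata, duplicate (species, marker) pairs and
    illegal sequence characters are hard errors.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    if list(meta.columns) != METADATA_COLUMNS:
        raise ValidationError(
            f"metadata {metadata_path}: expected columns {METADATA_COLUMNS}, "
            f"got {list(meta.columns)}"
        )
    if meta["record_id"].duplicated().any():
        dup = meta.loc[meta["record_id"].duplicated(), "record_id"].iloc[0]
        raise ValidationError(f"metadata: duplicate record_id {dup!r}")
    rows = meta.set_index("record_id")

    records = []
    for seqrec in SeqIO.parse(str(fasta_path), "fasta"):
        if seqrec.id not in rows.index:
            raise ValidationError(
                f"FASTA id {seqrec.id!r} has no row in {metadata_path}"
            )
        row = rows.loc[seqrec.id]
        records.append(
            ReferenceRecord(
                record_id=seqrec.id,
                species=row["species"],
                marker=row["marker"],
                status=row["status"],
                accession=row["accession"],
                sequence=str(seqrec.seq),
            )
        )
    return ReferenceDB(records)


def write_reference(
    db: ReferenceDB, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a database as FASTA (80-column wrap) + metadata TSV.

    Records are ordered by (species, marker) so output is byte-stable.
    """
    ordered = sorted(db.records, key=_sort_key)
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        for rec in ordered:
            writer.write_record(
                SeqRecord(Seq(rec.sequence), id=rec.record_id, description="")
            )
    pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "species": r.species,
                "marker": r.marker,
                "status": r.status,
                "accession": r.accession,
            }
            for r in ordered
        ],
        columns=METADATA_COLUMNS,
    ).to_csv(metadata_path, sep="\t", index=False)


def screen_rbcl_pseudogene(record: ReferenceRecord, frame: int) -> str:
    """Flag putative rbcL pseudogenes by reading-frame defects.

    Checks, in order: a frameshift (sequence length minus the frame offset is
    not a codon multiple → ``frameshift_indel``), then a premature stop codon
    in the translation of the stated frame (``internal_stop``); otherwise
    ``pass``. Undefined for the non-coding trnH-psbA spacer.
    """
    if record.marker != MARKER_RBCL:
        raise ValidationError(
            f"pseudogene screen is defined for {MARKER_RBCL} only, "
            f"got marker {record.marker!r}"
        )
    if frame not in (0, 1, 2):
        raise ValidationError(f"frame must be 0, 1 or 2, got {frame!r}")
    seq = record.sequence
    if len(seq) < 3:
        raise ValidationError(
            f"record {record.record_id!r}: sequence shorter than one codon"
        )
    if (len(seq) - frame) % 3 != 0:
        return "frameshift_indel"
    protein = str(Seq(seq[frame:]).translate())
    if "*" in protein[:-1]:
        return "internal_stop"
    return "pass"
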