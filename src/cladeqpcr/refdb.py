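"""Clade-annotated reference sequence databases.

A reference database pairs a multi-FASTA of marker-gene sequences with a
two-column tab-separated annotation mapping every sequence id to a clade
label. Clade labels are free-form strings matched exactly (case-sensitive);
the Accumulibacter ppk1 clade labels are available as a named preset in
:mod:`cladeqpcr.presets`. Sequences are upper-cased and U→T-normalized on
ingest so that all downstream matching happens over one alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .iupac import normalize


@dataclass(frozen=True)
class SequenceRecord:
    """One clade-annotated marker-gene sequence (reference strand, 5'→3')."""

    id: str
    clade: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        object.__setattr__(self, "seq", normalize(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceDatabase:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    @property
    def clades(self) -> set[str]:
        return {rec.clade for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)


def _read_annotation(annotation_path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(annotation_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(
                f"{annotation_path}:{lineno}: expected two tab-separated columns "
                f"(id, clade), got {line!r}"
            )
        rec_id, clade = parts
        if rec_id in mapping:
            raise ValueError(f"{annotation_path}:{lineno}: duplicate annotation for {rec_id!r}")
        mapping[rec_id] = clade
    return mapping


def _check_fasta_shape(fasta_path: str | Path) -> None:
    # SeqIO silently yields nothing for text before the first header; reject it
    # explicitly so a malformed file fails loudly with a line number.
    for lineno, line in enumerate(Path(fasta_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ValueError(
                f"{fasta_path}:{lineno}: malformed FASTA, expected '>' header first"
            )
        return


def read_database(fasta_path: str | Path, annotation_path: str | Path) -> ReferenceDatabase:
    """Read and validate a FASTA + annotation pair.

    Every FASTA id must be annotated and every annotated id must have a
    sequence; either mismatch is a validation error, as is a duplicate id.
    """
    _check_fasta_shape(fasta_path)
    annotation = _read_annotation(annotation_path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        if seq_rec.id in seen:
            raise ValueError(f"duplicate sequence id {seq_rec.id!r} in {fasta_path}")
        seen.add(seq_rec.id)
        if seq_rec.id not in annotation:
            raise ValueError(f"sequence {seq_rec.id!r} has no clade annotation")
        records.append(SequenceRecord(seq_rec.id, annotation[seq_rec.id], str(seq_rec.seq)))
    missing = set(annotation) - seen
    if missing:
        raise ValueError(f"annotated ids without a sequence: {sorted(missing)}")
    return ReferenceDatabase(records)


def write_database(
    db: ReferenceDatabase,
    fasta_path: str | Path,
    annotation_path: str | Path,
    line_width: int = 70,
) -> None:
    """Write a database back out as FASTA (wrapped) + annotation TSV."""
    with open(fasta_path, "w") as fh:
        for rec in db:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")
    with open(annotation_path, "w") as fh:
        fh.write("# id\tclade\n")
        for rec in db:
            fh.write(f"{rec.id}\t{rec.clade}\n")


def partition(
    db: ReferenceDatabase, target_clade: str
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split a database into (target, non-target) record lists.

    The target list holds exactly the records labelled ``target_clade``; every
    other record is a non-target, mirroring the successive target/non-target
    selection used when screening clade-specific primer candidates.
    """
    if target_clade not in db.clades:
        raise ValueError(
            f"unknown clade {target_clade!r}; available: {sorted(db.clades)}"
        )
    targets = [rec for rec in db if rec.clade == target_clade]
    nontargets = [rec for rec in db if rec.clade != target_clade]
    return targets, nontargets
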