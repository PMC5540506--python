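"""Sequence records and file I/O for the ncRNA classification pipeline.

The unit of data flowing through the pipeline is an :class:`NcRnaRecord`:
one RNA sequence, optionally annotated with a secondary structure in
(extended) dot-bracket notation and a class label.  Structures are produced
upstream by a secondary-structure predictor and consumed here as plain text;
three on-disk layouts are supported:

* FASTA for sequences (read via Biopython),
* the Vienna three-line layout (``>id`` / sequence / structure) for
  structures,
* a two-column TSV ``id<TAB>structure`` paired with a FASTA,
* a two-column TSV ``id<TAB>class`` label manifest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "NcRnaRecord",
    "normalize_sequence",
    "read_fasta",
    "read_structures",
    "read_structure_tsv",
    "read_labels",
    "attach_structures",
    "attach_labels",
    "write_fasta",
    "write_structures",
    "write_labels",
]

_ALPHABET = frozenset("ACGUN")


def normalize_sequence(raw: str) -> str:
    """Uppercase, DNA->RNA (T->U), and collapse anything else to N."""
    seq = raw.upper().replace("T", "U")
    return "".join(ch if ch in "ACGU" else "N" for ch in seq)


@dataclass(frozen=True)
class NcRnaRecord:
    """One ncRNA sequence with optional structure and class label."""

    id: str
    sequence: str
    structure: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: sequence contains non-normalized "
                f"characters {sorted(bad)}; apply normalize_sequence first"
            )
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def with_structure(self, structure: str) -> "NcRnaRecord":
        return replace(self, structure=structure)

    def with_label(self, label: str) -> "NcRnaRecord":
        return replace(self, class_label=label)


def read_fasta(path: str | Path) -> list[NcRnaRecord]:
    """Read a FASTA file into normalized records, preserving file order.

    Raises ``ValueError`` on an empty file, a duplicate id (named in the
    message), or sequence data appearing before any header (Biopython's
    FASTA parser rejects that layout).
    """
    records: list[NcRnaRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(
                NcRnaRecord(id=rec.id, sequence=normalize_sequence(str(rec.seq)))
            )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_structures(path: str | Path) -> dict[str, str]:
    """Read a Vienna three-line structure file: ``>id`` / sequence / structure."""
    structures: dict[str, str] = {}
    lines = [ln.rstrip("\n") for ln in open(path)]
    lines = [ln for ln in lines if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record {header!r}")
        rec_id = header[1:].split()[0]
        if rec_id in structures:
            raise ValueError(f"duplicate structure id {rec_id!r} in {path}")
        structures[rec_id] = lines[i + 2].split()[0]
        i += 3
    if not structures:
        raise ValueError(f"no structure records found in {path}")
    return structures


def read_structure_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>structure`` table (no header)."""
    structures: dict[str, str] = {}
    with open(path) as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row:
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: expected 2 columns, got {len(row)}")
            rec_id, struct = row
            if rec_id in structures:
                raise ValueError(f"duplicate structure id {rec_id!r} in {path}")
            structures[rec_id] = struct
    if not structures:
        raise ValueError(f"no structures found in {path}")
    return structures


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a label manifest TSV (``id<TAB>class``; optional header row)."""
    labels: dict[str, str] = {}
    with open(path) as handle:
        rows = list(csv.reader(handle, delimiter="\t"))
    if rows and rows[0] and rows[0][0].lower() in {"id", "sequence_id"}:
        rows = rows[1:]
    for row in rows:
        if not row:
            continue
        if len(row) != 2:
            raise ValueError(f"{path}: expected 2 columns, got {len(row)}")
        rec_id, label = row
        if rec_id in labels:
            raise ValueError(f"duplicate id {rec_id!r} in label manifest {path}")
        labels[rec_id] = label
    if not labels:
        raise ValueError(f"no labels found in {path}")
    return labels


def attach_structures(
    records: Sequence[NcRnaRecord], structures: dict[str, str]
) -> list[NcRnaRecord]:
    out = []
    for rec in records:
        if rec.id not in structures:
            raise ValueError(f"no structure for record {rec.id!r}")
        out.append(rec.with_structure(structures[rec.id]))
    return out


def attach_labels(
    records: Sequence[NcRnaRecord], labels: dict[str, str]
) -> list[NcRnaRecord]:
    out = []
    for rec in records:
        if rec.id not in labels:
            raise ValueError(f"no class label for record {rec.id!r}")
        out.append(rec.with_label(labels[rec.id]))
    return out


def write_fasta(records: Iterable[NcRnaRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.sequence}\n")


def write_structures(records: Iterable[NcRnaRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            if rec.structure is None:
                raise ValueError(f"record {rec.id!r} has no structure")
            handle.write(f">{rec.id}\n{rec.sequence}\n{rec.structure}\n")


def write_labels(records: Iterable[NcRnaRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("id\tclass\n")
        for rec in records:
            if rec.class_label is None:
                raise ValueError(f"record {rec.id!r} has no class label")
            handle.write(f"{rec.id}\t{rec.class_label}\n")
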