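"""Reading and writing the formats the pipeline touches.

Proteins come in as FASTA (any number of records, wrapped or unwrapped);
results go out as TSV/CSV/JSON tables with a fixed column order and fixed
numeric precision so that reruns are byte-identical.

Sequences are restricted to the 20 canonical one-letter amino-acid codes.
Ambiguity codes (B, J, O, U, X, Z) are rejected rather than mapped: cleavage
rules and catalogue matching are defined only on canonical residues, and a
silent substitution would corrupt downstream counts.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Decimal places used when serialising numbers to tables.
PERCENT_DECIMALS = 2
MASS_DECIMALS = 5
FREQUENCY_DECIMALS = 4


class SequenceError(ValueError):
    """A sequence contains a character outside the canonical alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence with provenance.

    Parameters
    ----------
    identifier : str
        Accession-like identifier; the first whitespace-delimited token of
        the FASTA header.
    description : str
        Everything after the first whitespace on the header line (may be
        empty).
    sequence : str
        Uppercase sequence over the canonical 20-letter alphabet.
    """

    identifier: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if not self.identifier:
            raise ValueError("protein identifier must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(raw: str) -> str:
    """Canonicalise an amino-acid sequence.

    Uppercases, strips whitespace and internal line breaks, and rejects any
    character outside the canonical 20-letter alphabet (including the
    ambiguity codes B, J, O, U, X and Z).

    Raises
    ------
    SequenceError
        If a non-residue character remains; the message names the offending
        character and its 1-based position in the cleaned sequence.
    """
    cleaned = "".join(str(raw).split()).upper()
    if not cleaned:
        raise SequenceError("sequence is empty after cleaning")
    for pos, ch in enumerate(cleaned, start=1):
        if ch not in CANONICAL_RESIDUES:
            raise SequenceError(
                f"invalid residue {ch!r} at position {pos}: only the 20 "
                "canonical amino-acid codes are accepted"
            )
    return cleaned


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Entry order is preserved. Identifiers must be unique within the file.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the file holds no records, an identifier repeats, or a sequence
        fails validation (the error names the offending record).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        try:
            rec = ProteinRecord(
                identifier=entry.id,
                description=entry.description[len(entry.id):].strip(),
                sequence=str(entry.seq),
            )
        except SequenceError as exc:
            raise SequenceError(f"record {entry.id!r}: {exc}") from exc
        if rec.identifier in seen:
            raise ValueError(f"duplicate identifier {rec.identifier!r} in {path}")
        seen.add(rec.identifier)
        records.append(rec)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta`."""
    path = Path(path)
    lines: list[str] = []
    for rec in records:
        header = rec.identifier
        if rec.description:
            header += f" {rec.description}"
        lines.append(f">{header}")
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i:i + width])
    _atomic_write_text(path, "\n".join(lines) + "\n")


def _format_value(value: object) -> object:
    if isinstance(value, bool):
        return value
    if isinstance(value, float):
        return round(value, MASS_DECIMALS)
    return value


def format_percent(value: float) -> float:
    """Round a percentage for table output (2 decimals)."""
    return round(float(value), PERCENT_DECIMALS)


def write_table(rows: Sequence[Mapping[str, object]], path: str | Path,
                fmt: str = "tsv",
                columns: Sequence[str] | None = None) -> None:
    """Write uniform records as a delimited or JSON table.

    All rows must share one schema; column order is the key order of the
    first row (or the explicit *columns* list), so output is deterministic.
    Floats are serialised to 5 decimals; callers round percentages to 2
    decimals first (:func:`format_percent`). An empty row list with an
    explicit *columns* list yields a header-only file.

    Writes atomically (temp file + rename).
    """
    if fmt not in {"tsv", "csv", "json"}:
        raise ValueError(f"unsupported table format: {fmt!r}")
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("empty row list needs an explicit column list")
        columns = list(rows[0].keys())
    for i, row in enumerate(rows):
        if list(row.keys()) != list(columns):
            raise ValueError(
                f"row {i} schema {list(row.keys())} differs from table "
                f"schema {list(columns)}"
            )
    formatted = [{k: _format_value(v) for k, v in row.items()} for row in rows]
    buf = io.StringIO()
    if fmt == "json":
        json.dump(formatted, buf, indent=2)
        buf.write("\n")
    else:
        writer = csv.DictWriter(
            buf, fieldnames=list(columns),
            delimiter="\t" if fmt == "tsv" else ",", lineterminator="\n",
        )
        writer.writeheader()
        writer.writerows(formatted)
    _atomic_write_text(Path(path), buf.getvalue())


def _atomic_write_text(path: Path, text: str) -> None:
    """Write via temp file + rename so partial runs never leave truncated output."""
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)
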