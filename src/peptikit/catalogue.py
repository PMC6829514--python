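"""Activity-annotated short-peptide catalogue with exact-sequence lookup.

The catalogue plays the role a bioactive-peptide database (such as
BIOPEP-UWM) plays in a hosted analysis: a table of short peptides, each
annotated with one or more activities ("ACE inhibitor", "DPP-IV inhibitor",
antioxidative, ...). Lookup is exact and direction-sensitive — a dipeptide
and its reversal are distinct entries and commonly carry different
activities (AE is a known DPP-IV inhibitor while EA inhibits ACE).

A small demo catalogue of literature-typical di- and tripeptides is bundled
for tests and examples (``bundled_catalogue``). It is a synthetic fixture,
NOT a copy of any hosted database; real analyses should load a
user-supplied catalogue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .io_formats import validate_sequence

logger = logging.getLogger(__name__)

#: Activity labels reported individually; everything else is grouped as
#: "other activities" in ranking reports.
PRIMARY_ACTIVITIES = ("ACE inhibitor", "DPP-IV inhibitor")
OTHER_ACTIVITIES_LABEL = "other activities"

_REQUIRED_COLUMNS = ("id", "sequence", "activity")


@dataclass(frozen=True)
class CatalogueEntry:
    """One activity annotation for one peptide sequence."""

    peptide: str
    activity: str
    entry_id: str
    reference: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide", validate_sequence(self.peptide))
        object.__setattr__(self, "activity", self.activity.strip())
        if not self.activity:
            raise ValueError(f"entry {self.entry_id!r}: empty activity label")


@dataclass
class PeptideCatalogue:
    """A collection of :class:`CatalogueEntry` with exact-match lookup.

    ``min_len`` (default 2) excludes single residues, which are usually not
    meaningful catalogue entries; pass ``min_len=1`` to keep them.
    """

    entries: list[CatalogueEntry]
    min_len: int = 2
    _index: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        kept: list[CatalogueEntry] = []
        for entry in self.entries:
            if len(entry.peptide) < self.min_len:
                raise ValueError(
                    f"entry {entry.entry_id!r}: peptide {entry.peptide!r} "
                    f"shorter than min_len={self.min_len}"
                )
            key = (entry.peptide, entry.activity)
            if key in seen:
                logger.warning(
                    "duplicate catalogue entry %s/%s collapsed", *key)
                continue
            seen.add(key)
            kept.append(entry)
        self.entries = kept
        index: dict[str, set[str]] = {}
        for entry in self.entries:
            index.setdefault(entry.peptide, set()).add(entry.activity)
        self._index = {p: frozenset(a) for p, a in index.items()}

    @property
    def activities(self) -> frozenset[str]:
        """All activity labels present in the catalogue."""
        return frozenset(e.activity for e in self.entries)

    @property
    def max_len(self) -> int:
        """Length of the longest entry peptide (0 for an empty catalogue)."""
        return max((len(e.peptide) for e in self.entries), default=0)

    @property
    def peptides(self) -> frozenset[str]:
        return frozenset(self._index)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, peptide: str) -> frozenset[str]:
        """Activities annotated to *peptide* (exact, direction-sensitive).

        Returns the empty set if the sequence is absent.
        """
        return self._index.get(validate_sequence(peptide), frozenset())


def load_catalogue(path: str | Path, min_len: int = 2) -> PeptideCatalogue:
    """Load a catalogue from a delimited text file.

    Expected format: TSV (CSV detected by a ``.csv`` suffix) with header
    columns ``id``, ``sequence``, ``activity`` and an optional
    ``reference``; UTF-8; lines starting with ``#`` are comments.
    Duplicate (sequence, activity) rows collapse with a logged warning.

    Raises
    ------
    ValueError
        If a required column is missing or a row fails sequence validation
        (the error names the row).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    entries: list[CatalogueEntry] = []
    for i, row in df.iterrows():
        try:
            entries.append(CatalogueEntry(
                peptide=row["sequence"],
                activity=row["activity"],
                entry_id=row["id"],
                reference=row.get("reference", ""),
            ))
        except ValueError as exc:
            raise ValueError(f"{path} row {i + 2}: {exc}") from exc
    return PeptideCatalogue(entries, min_len=min_len)


def bundled_catalogue() -> PeptideCatalogue:
    """The bundled demo catalogue of literature-typical bioactive peptides.

    A synthetic fixture for tests and examples — it is not, and does not
    approximate, the contents of any versioned hosted database, so absolute
    hit counts computed against it are not comparable with published counts.
    """
    with resources.as_file(
        resources.files("peptikit.data") / "catalogue_demo.tsv"
    ) as p:
        return load_catalogue(p)
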