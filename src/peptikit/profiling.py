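"""Bioactive-peptide profiling of proteins and digests.

Three computations mirror the tool chain of hosted bioactive-peptide
databases:

* :func:`profile_protein` — the "profile of potential biological activity":
  every catalogue peptide occurring anywhere as a substring of the protein,
  with locations and per-activity occurrence counts.
* :func:`active_fragments` — the "search for active fragments" applied to a
  simulated digest: each *released* peptide is looked up as a whole; a
  bioactive sequence buried inside a longer released fragment is not a hit.
  This whole-fragment semantics is the main interpretive choice of the
  module and matches how released-peptide searches behave.
* :func:`rank_enzymes` — per-enzyme, per-activity totals over a protein
  set, identifying which protease theoretically releases the most
  bioactive peptides.

Counts are occurrence counts by default: overlapping matches and repeated
instances of the same peptide each count once per occurrence (a dipeptide
released twice counts twice). Distinct-peptide counting is available via
``distinct=True``; reports label the mode in their metadata.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .catalogue import (OTHER_ACTIVITIES_LABEL, PRIMARY_ACTIVITIES,
                        PeptideCatalogue)
from .io_formats import ProteinRecord
from .proteolysis import RULESET_VERSION, Enzyme, Fragment, digest


@dataclass(frozen=True)
class ActivityHit:
    """One catalogue peptide found at one location (1-based inclusive)."""

    peptide: str
    activity: str
    start: int
    end: int


@dataclass
class ActivityProfile:
    """All catalogue peptides occurring as substrings of one protein."""

    protein_id: str
    hits: list[ActivityHit]
    counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.counts = dict(Counter(h.activity for h in self.hits))

    def distinct_counts(self) -> dict[str, int]:
        """Per-activity counts of distinct peptide sequences."""
        return {a: len({h.peptide for h in self.hits if h.activity == a})
                for a in self.counts}


@dataclass
class DigestReport:
    """Released fragments of one digest annotated against a catalogue."""

    protein_id: str
    enzyme: str
    ruleset_version: str
    fragments: list[Fragment]
    active_hits: list[tuple[Fragment, frozenset[str]]]
    counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        counter: Counter[str] = Counter()
        for _, activities in self.active_hits:
            counter.update(activities)
        self.counts = dict(counter)

    def distinct_counts(self) -> dict[str, int]:
        """Per-activity counts of distinct released sequences."""
        out: dict[str, set[str]] = {}
        for frag, activities in self.active_hits:
            for act in activities:
                out.setdefault(act, set()).add(frag.sequence)
        return {a: len(s) for a, s in out.items()}


def profile_protein(protein: ProteinRecord,
                    catalogue: PeptideCatalogue) -> ActivityProfile:
    """Locate every catalogue peptide occurring in the protein sequence.

    Enumeration scans all substrings of length ``min_len..max_len`` of the
    catalogue; overlapping and repeated occurrences are all reported. Hits
    are ordered by ``(start, end, activity)``.
    """
    seq = protein.sequence
    hits: list[ActivityHit] = []
    lengths = range(catalogue.min_len, min(catalogue.max_len, len(seq)) + 1)
    for start0 in range(len(seq)):
        for length in lengths:
            if start0 + length > len(seq):
                break
            sub = seq[start0:start0 + length]
            for activity in catalogue.lookup(sub):
                hits.append(ActivityHit(
                    peptide=sub, activity=activity,
                    start=start0 + 1, end=start0 + length))
    hits.sort(key=lambda h: (h.start, h.end, h.activity))
    return ActivityProfile(protein_id=protein.identifier, hits=hits)


def active_fragments(fragments: list[Fragment],
                     catalogue: PeptideCatalogue,
                     protein_id: str | None = None,
                     enzyme_name: str = "",
                     ruleset_version: str = RULESET_VERSION) -> DigestReport:
    """Annotate released fragments by whole-fragment catalogue lookup.

    Each fragment instance contributes one count per activity annotated to
    its full sequence; fragments whose sequence is absent from the
    catalogue contribute nothing.
    """
    if protein_id is None:
        protein_id = fragments[0].parent_id if fragments else ""
    active = []
    for frag in fragments:
        activities = catalogue.lookup(frag.sequence) if len(frag) else frozenset()
        if activities:
            active.append((frag, activities))
    return DigestReport(
        protein_id=protein_id, enzyme=enzyme_name,
        ruleset_version=ruleset_version,
        fragments=list(fragments), active_hits=active)


def frequency_of_occurrence(profile: ActivityProfile,
                            protein: ProteinRecord) -> dict[str, float]:
    """Per-activity occurrence count divided by protein length.

    The classic "A" parameter of bioactive-peptide profiling; values are
    reported to 4 decimals in tables.
    """
    if profile.protein_id != protein.identifier:
        raise ValueError("profile was computed from a different protein")
    n = len(protein)
    return {activity: count / n for activity, count in profile.counts.items()}


def rank_enzymes(proteins: list[ProteinRecord], enzymes: list[Enzyme],
                 catalogue: PeptideCatalogue,
                 primary_activities: tuple[str, ...] = PRIMARY_ACTIVITIES,
                 distinct: bool = False) -> list[dict[str, object]]:
    """Per-enzyme bioactive-release totals over a set of proteins.

    Every protein is digested to completion by every enzyme and the
    released fragments are annotated against the catalogue. Activities
    outside *primary_activities* are merged under one "other activities"
    label. Rows are ordered by descending total (ties broken by enzyme
    name), so the first row's enzyme is the theoretically most productive
    protease; each row carries the per-activity breakdown and the counting
    mode.
    """
    rows = []
    for enzyme in enzymes:
        totals: Counter[str] = Counter()
        for protein in proteins:
            report = active_fragments(
                digest(protein, enzyme), catalogue,
                protein_id=protein.identifier, enzyme_name=enzyme.name)
            counts = report.distinct_counts() if distinct else report.counts
            for activity, count in counts.items():
                key = (activity if activity in primary_activities
                       else OTHER_ACTIVITIES_LABEL)
                totals[key] += count
        row: dict[str, object] = {"enzyme": enzyme.name}
        for activity in primary_activities:
            row[activity] = totals.get(activity, 0)
        row[OTHER_ACTIVITIES_LABEL] = totals.get(OTHER_ACTIVITIES_LABEL, 0)
        row["total"] = sum(totals.values())
        row["counting"] = "distinct" if distinct else "instances"
        rows.append(row)
    rows.sort(key=lambda r: (-int(r["total"]), str(r["enzyme"])))
    return rows
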