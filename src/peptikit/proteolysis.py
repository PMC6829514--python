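"""Declarative enzyme-specificity rules and an in-silico digestion engine.

Cleavage specificity is expressed in Schechter–Berger positional terms: P1
is the residue on the N-terminal side of the scissile bond, P1' the residue
on the C-terminal side, P2 the residue before P1. A :class:`CleavageRule`
fires at a bond iff

    (P1 in p1_allow  or  P2 in p2_allow, when p2_allow is set)
    and P1 not in p1_block
    and (p1prime_allow empty or P1' in p1prime_allow)
    and P1' not in p1prime_block

and an :class:`Enzyme` cleaves where any of its rules fires. This grammar
covers the classic Keil-style rule tables (e.g. trypsin: P1 in {K, R}
except before proline) without free-form regular expressions.

Digestion is complete by default — every fireable bond is cut, which is
the convention hosted "enzyme action" simulators use. Missed cleavages
(bounded numbers of internal uncut sites, as allowed in MS database
searches) are available through ``max_missed``.

The bundled enzyme table is an editorial reconstruction of standard
PeptideCutter/Keil-style specificities, versioned via
:data:`RULESET_VERSION` and fully overridable through
:func:`parse_enzyme_config`; the stem-bromelain rule in particular is a
low-confidence convention, since no authoritative protein-substrate rule
exists for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .io_formats import CANONICAL_RESIDUES, ProteinRecord

#: Version stamp of the bundled cleavage-rule table; echoed in all reports
#: so results are reproducible against a declared rule set.
RULESET_VERSION = "peptikit-rules-1.0"

_RULE_KEYS = ("p1_allow", "p1_block", "p1prime_allow", "p1prime_block",
              "p2_allow")


def _residue_set(value: object, key: str) -> frozenset[str]:
    if value is None:
        return frozenset()
    if isinstance(value, str):
        residues = list(value.replace(",", "").replace(" ", ""))
    else:
        residues = [str(v) for v in value]
    out = frozenset(r.upper() for r in residues)
    bad = out - CANONICAL_RESIDUES
    if bad:
        raise ValueError(f"{key}: non-canonical residue(s) {sorted(bad)}")
    return out


@dataclass(frozen=True)
class CleavageRule:
    """One positional specificity pattern (see module docstring for semantics)."""

    p1_allow: frozenset[str] = frozenset()
    p1_block: frozenset[str] = frozenset()
    p1prime_allow: frozenset[str] = frozenset()
    p1prime_block: frozenset[str] = frozenset()
    p2_allow: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for key in _RULE_KEYS:
            object.__setattr__(self, key, _residue_set(getattr(self, key), key))
        if self.p1_allow & self.p1_block:
            raise ValueError(
                f"p1_allow and p1_block overlap: {sorted(self.p1_allow & self.p1_block)}")
        if self.p1prime_allow & self.p1prime_block:
            raise ValueError(
                "p1prime_allow and p1prime_block overlap: "
                f"{sorted(self.p1prime_allow & self.p1prime_block)}")

    def fires(self, p1: str, p1prime: str, p2: str | None) -> bool:
        """Does this rule cleave the bond with the given positional context?

        *p2* is ``None`` when the bond follows the first residue (no P2
        position exists); a P2-based trigger then cannot fire.
        """
        triggered = p1 in self.p1_allow or (
            bool(self.p2_allow) and p2 is not None and p2 in self.p2_allow)
        if not triggered or p1 in self.p1_block:
            return False
        if self.p1prime_allow and p1prime not in self.p1prime_allow:
            return False
        return p1prime not in self.p1prime_block


@dataclass(frozen=True)
class Enzyme:
    """A named protease: cleaves at a bond iff any of its rules fires."""

    name: str
    ec_number: str = ""
    rules: tuple[CleavageRule, ...] = ()

    def cleaves(self, p1: str, p1prime: str, p2: str | None) -> bool:
        return any(rule.fires(p1, p1prime, p2) for rule in self.rules)


@dataclass(frozen=True)
class Fragment:
    """A peptide released from a parent protein.

    ``start`` and ``end`` are 1-based inclusive residue coordinates;
    ``n_missed`` counts internal sites that were left uncleaved.
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    n_missed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad fragment coordinates {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("fragment sequence length does not match coordinates")
        if self.n_missed < 0:
            raise ValueError("n_missed must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(protein: ProteinRecord, enzyme: Enzyme) -> list[int]:
    """All bonds the enzyme cleaves, as sorted 1-based site positions.

    Site ``i`` is the bond between residues ``i`` and ``i + 1``; valid
    sites lie in ``[1, len - 1]``.
    """
    seq = protein.sequence
    sites = []
    for i in range(1, len(seq)):
        p2 = seq[i - 2] if i >= 2 else None
        if enzyme.cleaves(seq[i - 1], seq[i], p2):
            sites.append(i)
    return sites


def digest(protein: ProteinRecord, enzyme: Enzyme,
           max_missed: int = 0) -> list[Fragment]:
    """Complete digestion of one protein, optionally with missed cleavages.

    With ``max_missed=0`` the fragments partition the parent (their
    concatenation restores the sequence). With ``max_missed=m`` every run
    of up to ``m + 1`` consecutive zero-missed fragments is additionally
    emitted, with ``n_missed`` set to the number of internal uncut sites.
    Fragments are ordered by ``(start, end)``.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    sites = cleavage_sites(protein, enzyme)
    return _fragments_from_sites(protein, sites, max_missed)


def digest_sequential(protein: ProteinRecord,
                      enzymes: list[Enzyme]) -> list[Fragment]:
    """Sequential multi-enzyme digestion (e.g. Lys-C followed by trypsin).

    With complete digestion the order of application does not matter: the
    result is a single cut at the union of each enzyme's site set, and the
    fragments partition the parent.
    """
    if not enzymes:
        raise ValueError("digest_sequential needs at least one enzyme")
    sites: set[int] = set()
    for enzyme in enzymes:
        sites.update(cleavage_sites(protein, enzyme))
    return _fragments_from_sites(protein, sorted(sites), max_missed=0)


def _fragments_from_sites(protein: ProteinRecord, sites: list[int],
                          max_missed: int) -> list[Fragment]:
    seq = protein.sequence
    bounds = [0, *sites, len(seq)]  # 0-based half-open piece boundaries
    n_pieces = len(bounds) - 1
    frags = []
    for i in range(n_pieces):
        for j in range(i, min(i + max_missed + 1, n_pieces)):
            lo, hi = bounds[i], bounds[j + 1]
            frags.append(Fragment(
                parent_id=protein.identifier,
                start=lo + 1, end=hi,
                sequence=seq[lo:hi],
                n_missed=j - i,
            ))
    frags.sort(key=lambda f: (f.start, f.end))
    return frags


# ---------------------------------------------------------------------------
# Enzyme registry

class EnzymeRegistry(dict):
    """Name → :class:`Enzyme` mapping with a helpful unknown-name error."""

    def get_enzyme(self, name: str) -> Enzyme:
        try:
            return self[name]
        except KeyError:
            known = ", ".join(sorted(self))
            raise KeyError(
                f"unknown enzyme {name!r}; registered enzymes: {known}"
            ) from None


def _parse_enzyme_entry(name: str, spec: dict) -> Enzyme:
    spec = dict(spec or {})
    ec = str(spec.pop("ec", ""))
    raw_rules = spec.pop("rules", None)
    if raw_rules is None:
        raw_rules = [spec] if spec else []
        spec = {}
    unknown = set(spec) - set(_RULE_KEYS)
    if unknown:
        raise ValueError(f"enzyme {name!r}: unknown key(s) {sorted(unknown)}")
    rules = []
    for rule_spec in raw_rules:
        unknown = set(rule_spec) - set(_RULE_KEYS)
        if unknown:
            raise ValueError(
                f"enzyme {name!r}: unknown rule key(s) {sorted(unknown)}")
        rules.append(CleavageRule(**{k: rule_spec.get(k) for k in _RULE_KEYS
                                     if rule_spec.get(k) is not None}))
    return Enzyme(name=name, ec_number=ec, rules=tuple(rules))


def parse_enzyme_config(path: str | Path | None = None) -> EnzymeRegistry:
    """Build the enzyme registry, merging a user config over the defaults.

    The config is YAML: a mapping ``enzymes: {<name>: {ec: ..., p1_allow:
    "KR", p1prime_block: "P", ...}}`` where rule position keys may sit
    directly on the enzyme (single rule) or under a ``rules:`` list.
    Residue sets are strings of one-letter codes. User definitions override
    bundled ones by name.

    With ``path=None`` the bundled defaults alone are returned.
    """
    registry = EnzymeRegistry()
    with resources.as_file(resources.files("peptikit.data") / "enzymes.yaml") as p:
        _merge_config(registry, yaml.safe_load(p.read_text()))
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            _merge_config(registry, loaded)
    return registry


def _merge_config(registry: EnzymeRegistry, config: dict | None) -> None:
    if not config:
        return
    enzymes = config.get("enzymes", config)
    for name, spec in enzymes.items():
        registry[name] = _parse_enzyme_entry(name, spec)


def default_registry() -> EnzymeRegistry:
    """The bundled enzyme registry (rule-set :data:`RULESET_VERSION`)."""
    return parse_enzyme_config(None)
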