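"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's digestion/profiling code paths:
rule evaluation is re-coded directly from the positional semantics, and
profiling scans every substring against a plain dict.
"""

from __future__ import annotations


def bond_cleaves(seq: str, i: int, enzyme) -> bool:
    """Does *enzyme* cleave the bond after 1-based residue position i?

    Direct transcription of the rule semantics: a rule fires iff P1 is in
    p1_allow (or P2 is in a nonempty p2_allow), P1 is not blocked, and P1'
    passes its allow/block constraints.
    """
    p1 = seq[i - 1]
    p1prime = seq[i]
    p2 = seq[i - 2] if i >= 2 else None
    for rule in enzyme.rules:
        trig = p1 in rule.p1_allow
        if rule.p2_allow and p2 is not None and p2 in rule.p2_allow:
            trig = True
        if not trig:
            continue
        if p1 in rule.p1_block:
            continue
        if rule.p1prime_allow and p1prime not in rule.p1prime_allow:
            continue
        if p1prime in rule.p1prime_block:
            continue
        return True
    return False


def brute_force_sites(seq: str, enzyme) -> list[int]:
    return [i for i in range(1, len(seq)) if bond_cleaves(seq, i, enzyme)]


def brute_force_digest(seq: str, enzyme) -> list[tuple[int, int, str]]:
    """Zero-missed fragments as (start, end, sequence), 1-based inclusive."""
    cuts = [0, *brute_force_sites(seq, enzyme), len(seq)]
    return [(cuts[i] + 1, cuts[i + 1], seq[cuts[i]:cuts[i + 1]])
            for i in range(len(cuts) - 1)]


def brute_force_missed(seq: str, enzyme, max_missed: int
                       ) -> list[tuple[int, int, str, int]]:
    """All fragments with up to max_missed internal sites, via enumeration
    of consecutive zero-missed runs."""
    pieces = brute_force_digest(seq, enzyme)
    out = []
    for i in range(len(pieces)):
        for j in range(i, min(i + max_missed + 1, len(pieces))):
            start = pieces[i][0]
            end = pieces[j][1]
            out.append((start, end, seq[start - 1:end], j - i))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def brute_force_profile(seq: str, annotations: dict[str, set[str]]
                        ) -> list[tuple[str, str, int, int]]:
    """All (peptide, activity, start, end) hits by scanning every substring."""
    hits = []
    for start0 in range(len(seq)):
        for end0 in range(start0 + 1, len(seq) + 1):
            sub = seq[start0:end0]
            for activity in annotations.get(sub, ()):
                hits.append((sub, activity, start0 + 1, end0))
    hits.sort(key=lambda h: (h[2], h[3], h[1]))
    return hits
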