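"""Trajectory-pattern classification of three-group analyte profiles.

Each analyte's trajectory across the trio (W = normal, P = precancerous,
T = tumor) is summarized by three pairwise relations — T vs P, T vs W and
P vs W — where ``>``/``<`` mean a significant difference at alpha and ``=``
means "not significant", not numerically equal. An exact-match lookup on the
relation triple assigns one of four categories:

* ``HCC_pos`` / ``HCC_neg``: tumor tissue sits significantly above / below
  the other two groups (tumor-associated change);
* ``RAS_pos`` / ``RAS_neg``: both oncogene-bearing tissues (P and T) sit
  significantly above / below normal (oncogene-associated change);

each with the enumerated subtypes below. Any other triple is unclassified.
Chain subtypes (e.g. ``T>W>P``) require the implied outer inequality to be
significant too; profiles whose adjacent relations are significant but whose
outer relation is not are flagged ``consistent=False`` and left
unclassified — exact-match semantics is the only deterministic reading of a
strict chain under noise.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .differential import PairwiseResult

__all__ = [
    "TrajectoryProfile",
    "PatternCall",
    "PATTERN_TABLE",
    "build_trajectory",
    "classify_pattern",
    "classify_table",
    "ProfileError",
]


class ProfileError(ValueError):
    pass


_MIRROR = {">": "<", "<": ">", "=": "="}

#: relation triple (top vs mid, top vs base, mid vs base) -> (category, subtype
#: template). Templates are rendered with the actual group labels; the
#: defaults give e.g. "T>P=W".
PATTERN_TABLE: Mapping[tuple[str, str, str], tuple[str, str]] = {
    (">", ">", "="): ("HCC_pos", "{t}>{p}={w}"),
    (">", ">", "<"): ("HCC_pos", "{t}>{w}>{p}"),
    (">", "<", "<"): ("HCC_pos", "{w}>{t}>{p}"),
    ("<", "<", "="): ("HCC_neg", "{t}<{p}={w}"),
    ("<", "<", ">"): ("HCC_neg", "{t}<{w}<{p}"),
    ("<", ">", ">"): ("HCC_neg", "{w}<{t}<{p}"),
    (">", ">", ">"): ("RAS_pos", "{t}>{p}>{w}"),
    ("=", ">", ">"): ("RAS_pos", "{t}={p}>{w}"),
    ("<", "<", "<"): ("RAS_neg", "{t}<{p}<{w}"),
    ("=", "<", "<"): ("RAS_neg", "{t}={p}<{w}"),
}

# Triples whose two significant relations form a chain while the implied
# outer inequality is not significant — transitively inconsistent.
_INCONSISTENT = {
    ("=", ">", "<"),  # T>W and W>P but T vs P not significant
    ("=", "<", ">"),
    (">", "=", ">"),  # T>P and P>W but T vs W not significant
    ("<", "=", "<"),
    (">", "<", "="),  # W>T and T>P but W vs P not significant
    ("<", ">", "="),
}


@dataclasses.dataclass
class TrajectoryProfile:
    """Per-analyte group means plus the three oriented relations.

    Relations are oriented as (top vs mid, top vs base, mid vs base) for the
    trio ``(base, mid, top)`` — with the default W/P/T trio: rel_tp = T vs P,
    rel_tw = T vs W, rel_pw = P vs W.
    """

    analyte_id: str
    mean_base: float
    mean_mid: float
    mean_top: float
    rel_tp: str
    rel_tw: str
    rel_pw: str
    groups: tuple[str, str, str] = ("W", "P", "T")

    def __post_init__(self) -> None:
        for r in (self.rel_tp, self.rel_tw, self.rel_pw):
            if r not in (">", "<", "="):
                raise ProfileError(f"invalid relation {r!r}")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.rel_tp, self.rel_tw, self.rel_pw)


@dataclasses.dataclass
class PatternCall:
    analyte_id: str
    category: str  # HCC_pos | HCC_neg | RAS_pos | RAS_neg | unclassified
    subtype: str  # canonical string such as "T>P=W"; "" if unclassified
    consistent: bool = True


def build_trajectory(
    results: Sequence[PairwiseResult],
    groups: tuple[str, str, str] = ("W", "P", "T"),
) -> TrajectoryProfile:
    """Assemble one analyte's profile from its three pairwise comparisons.

    Exactly the three comparisons (base, mid), (mid, top) and (base, top)
    must be present, in either orientation; they are re-oriented into
    (top vs mid, top vs base, mid vs base).
    """
    base, mid, top = groups
    by_pair: dict[frozenset, PairwiseResult] = {}
    analytes = {r.analyte_id for r in results}
    if len(analytes) != 1:
        raise ProfileError(f"results span several analytes: {sorted(analytes)}")
    for r in results:
        by_pair[frozenset((r.group_a, r.group_b))] = r

    def oriented(first: str, second: str) -> str:
        key = frozenset((first, second))
        if key not in by_pair:
            raise ProfileError(f"missing comparison {first} vs {second}")
        r = by_pair[key]
        return r.relation if r.group_a == first else _MIRROR[r.relation]

    def mean_of(group: str) -> float:
        for r in results:
            if r.group_a == group:
                return r.mean_a
            if r.group_b == group:
                return r.mean_b
        raise ProfileError(f"group {group!r} absent from results")

    return TrajectoryProfile(
        analyte_id=next(iter(analytes)),
        mean_base=mean_of(base),
        mean_mid=mean_of(mid),
        mean_top=mean_of(top),
        rel_tp=oriented(top, mid),
        rel_tw=oriented(top, base),
        rel_pw=oriented(mid, base),
        groups=groups,
    )


def classify_pattern(profile: TrajectoryProfile) -> PatternCall:
    """Exact-match classification of the relation triple (a total function)."""
    base, mid, top = profile.groups
    triple = profile.triple
    hit = PATTERN_TABLE.get(triple)
    if hit is None:
        return PatternCall(
            analyte_id=profile.analyte_id,
            category="unclassified",
            subtype="",
            consistent=triple not in _INCONSISTENT,
        )
    category, template = hit
    return PatternCall(
        analyte_id=profile.analyte_id,
        category=category,
        subtype=template.format(w=base, p=mid, t=top),
        consistent=True,
    )


def classify_table(
    profiles: Iterable[TrajectoryProfile],
) -> tuple[list[PatternCall], Counter]:
    """Classify every profile; return the calls and (category, subtype) counts."""
    calls = [classify_pattern(p) for p in profiles]
    counts = Counter((c.category, c.subtype) for c in calls)
    return calls, counts
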