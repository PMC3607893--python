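"""Variants relative to the reference, in the field's label notation.

A variant is a single difference from the reference at a 1-based rCRS
position.  Labels follow the conventional control-region notation:

* substitutions: position + derived base, e.g. ``"16223T"``; a trailing
  ``"!"`` marks a back-mutation (reversion to an ancestral state that is
  itself the reference base at that position), e.g. ``"16278C!"``
* deletions: ``"498delC"`` (deleted reference bases after ``del``)
* insertions: ``"523insCA"`` (inserted bases after ``ins``, keyed to the
  preceding reference position)

``parse_variant_label`` and ``format_variant`` are inverse bijections on
canonical labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

_LABEL_RE = re.compile(
    r"^(?P<pos>\d+)"
    r"(?:(?P<indel>ins|del)(?P<bases>[ACGT]+)|(?P<base>[ACGT])(?P<rev>!)?)$"
)


@dataclass(frozen=True, order=True)
class Variant:
    """One difference from the reference."""

    position: int
    kind: str
    state: str  # derived base for subs; inserted/deleted bases for indels
    reversion: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == SUBSTITUTION and len(self.state) != 1:
            raise ValueError("substitution state must be a single base")
        if self.reversion and self.kind != SUBSTITUTION:
            raise ValueError("reversion flag only applies to substitutions")
        if not re.fullmatch(r"[ACGT]+", self.state):
            raise ValueError(f"invalid state {self.state!r}")

    @property
    def label(self) -> str:
        return format_variant(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def format_variant(v: Variant) -> str:
    if v.kind == SUBSTITUTION:
        return f"{v.position}{v.state}{'!' if v.reversion else ''}"
    if v.kind == INSERTION:
        return f"{v.position}ins{v.state}"
    return f"{v.position}del{v.state}"


def parse_variant_label(label: str) -> Variant:
    """Parse a canonical variant label; raises ValueError naming the token."""
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed variant label: {label!r}")
    pos = int(m.group("pos"))
    if m.group("indel") == "ins":
        return Variant(pos, INSERTION, m.group("bases"))
    if m.group("indel") == "del":
        return Variant(pos, DELETION, m.group("bases"))
    return Variant(pos, SUBSTITUTION, m.group("base"), reversion=bool(m.group("rev")))


def parse_variants(labels: Iterable[str]) -> tuple[Variant, ...]:
    return tuple(sorted(parse_variant_label(x) for x in labels))


def variant_key(variants: Iterable[Variant]) -> tuple[str, ...]:
    """Deterministic lexicographic key for a variant set (by position, label)."""
    return tuple(v.label for v in sorted(set(variants)))
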