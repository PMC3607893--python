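"""Pairwise haplotype distances under the fifth-state convention.

The distance between two haplotypes is the (optionally position-weighted)
size of the symmetric difference of their variant-label sets: every
substitution and every indel event counts as one step at its position's
weight.  This is a metric (a weighted Hamming distance on indicator
vectors) and is the single distance used by the diversity, mismatch,
network and structure modules.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

from .sequences import HaplotypeProfile

#: optional weighting profile down-weighting hypermutable sites
HYPERMUTABLE_WEIGHTS: dict[int, float] = {16189: 0.5, 523: 0.5, 573: 0.5}

_POS_RE = re.compile(r"^(\d+)")


def _position(label: str) -> int:
    m = _POS_RE.match(label)
    if m is None:
        raise ValueError(f"cannot read position from label {label!r}")
    return int(m.group(1))


def _labels(x) -> frozenset[str]:
    if isinstance(x, HaplotypeProfile):
        return x.labels()
    if isinstance(x, frozenset):
        return x
    return frozenset(str(v) for v in x)


def weighted_distance(
    a: HaplotypeProfile | Iterable[str],
    b: HaplotypeProfile | Iterable[str],
    weights: Mapping[int, float] | None = None,
) -> float:
    """Weighted symmetric-difference distance between two haplotypes."""
    la, lb = _labels(a), _labels(b)
    if weights is None:
        return float(len(la ^ lb))
    total = 0.0
    for lab in la ^ lb:
        w = weights.get(_position(lab), 1.0)
        if w <= 0:
            raise ValueError(f"non-positive weight for position {_position(lab)}")
        total += w
    return total
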