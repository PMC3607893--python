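"""Control-region reference segments.

The coordinate system is 1-based rCRS numbering.  Two hypervariable
segments are analyzed: HVS-I (positions 15997-16569, 573 bp) and HVS-II
(positions 57-607, 551 bp), 1124 bp combined.

The default reference shipped here is a *synthetic* stand-in for the rCRS
control region: a deterministic pseudo-random base sequence that carries
the real structural features the variant-normalization rules depend on
(the 303-315 poly-C tract interrupted by 310T, the 568-573 C tract, the
515-524 CA-repeat, and the 16184-16193 poly-C context).  Every analysis in
the package is reference-relative, so results on synthetic or user data do
not depend on the stand-in's base identities.  Users with the real rCRS can
construct :class:`ReferenceSegments` from their own sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HVS1_RANGE = (15997, 16569)
HVS2_RANGE = (57, 607)

#: HVS-II poly-C repeat tract excluded from all variant calls.
EXCLUDED_TRACT = (303, 315)
#: HVS-II poly-C tract whose insertions collapse to a single C insertion.
POLYC_568_573 = (568, 573)
#: HVS-II "AC"-repeat region; length variants are recorded as 523ins/delCA.
CA_REPEAT_REGION = (515, 524)
#: HVS-I tract where substitution/indel ambiguity resolves to substitution.
AMBIGUOUS_16184_16193 = (16184, 16193)

_BASES = "ACGT"

# Ancestral (reference) bases pinned at the positions the shipped motif
# table uses, so that every motif label names a state that differs from the
# reference -- as the notation requires.  Values follow the rCRS where the
# notation implies it (e.g. "16223T" implies a non-T reference base).
_MOTIF_REF_BASES = {
    16223: "C", 16278: "C", 16311: "T", 16148: "C", 16172: "T",
    16320: "C", 16243: "T", 16214: "C", 16166: "A", 151: "C",
    16209: "T", 16274: "G", 16129: "G", 16399: "A", 498: "C",
    16179: "C", 16163: "A", 16294: "C", 16249: "T", 16234: "C",
    16212: "A", 597: "C", 16390: "G", 16069: "C", 16169: "C",
    188: "A", 294: "T", 16187: "C", 16192: "C", 16124: "T",
    16362: "T", 16330: "T", 16048: "G", 489: "T", 150: "C",
    16519: "T", 455: "T", 16300: "A", 16239: "C", 198: "C",
    # run boundaries, so repeat tracts end where the coordinates say they do
    302: "A", 316: "G", 567: "T", 574: "A", 525: "T",
    16183: "A", 16194: "T", 456: "A",
}


def _synthetic_segment(lo: int, hi: int, seed: int) -> str:
    """Deterministic synthetic reference bases for positions lo..hi."""
    rng = np.random.default_rng(seed)
    n = hi - lo + 1
    # mtDNA control region is C-rich on the L strand
    seq = list(rng.choice(list(_BASES), size=n, p=[0.31, 0.31, 0.13, 0.25]))

    def put(pos: int, base: str) -> None:
        if lo <= pos <= hi:
            seq[pos - lo] = base

    if lo <= 315 and hi >= 303:  # HVS-II
        for p in range(303, 316):
            put(p, "C")
        put(310, "T")
        for p in range(568, 574):
            put(p, "C")
        for p in range(515, 525):  # AC repeat written as ...CACACA... ending at 524
            put(p, "A" if (524 - p) % 2 else "C")
    if lo <= 16193 and hi >= 16184:  # HVS-I
        for p in range(16184, 16194):
            put(p, "C")
        put(16189, "T")
    for p, base in _MOTIF_REF_BASES.items():
        put(p, base)
    return "".join(seq)


@dataclass(frozen=True)
class ReferenceSegments:
    """The two control-region segments with their rCRS coordinates."""

    hvs1_range: tuple[int, int] = HVS1_RANGE
    hvs2_range: tuple[int, int] = HVS2_RANGE
    hvs1_seq: str = field(default="")
    hvs2_seq: str = field(default="")

    def __post_init__(self) -> None:
        if not self.hvs1_seq:
            object.__setattr__(
                self, "hvs1_seq", _synthetic_segment(*self.hvs1_range, seed=161)
            )
        if not self.hvs2_seq:
            object.__setattr__(
                self, "hvs2_seq", _synthetic_segment(*self.hvs2_range, seed=57)
            )
        for (lo, hi), seq in (
            (self.hvs1_range, self.hvs1_seq),
            (self.hvs2_range, self.hvs2_seq),
        ):
            if len(seq) != hi - lo + 1:
                raise ValueError(
                    f"segment {lo}-{hi} needs {hi - lo + 1} bases, got {len(seq)}"
                )

    @property
    def total_length(self) -> int:
        return len(self.hvs1_seq) + len(self.hvs2_seq)

    def segments(self) -> tuple[tuple[str, tuple[int, int], str], ...]:
        return (
            ("HVS1", self.hvs1_range, self.hvs1_seq),
            ("HVS2", self.hvs2_range, self.hvs2_seq),
        )

    def segment_of(self, position: int) -> str:
        for name, (lo, hi), _ in self.segments():
            if lo <= position <= hi:
                return name
        raise ValueError(f"position {position} outside both reference segments")

    def base_at(self, position: int) -> str:
        for _, (lo, hi), seq in self.segments():
            if lo <= position <= hi:
                return seq[position - lo]
        raise ValueError(f"position {position} outside both reference segments")

    def positions(self) -> list[int]:
        """All reference positions, HVS-II first then HVS-I order is NOT used:
        positions are returned in ascending rCRS coordinate order."""
        lo2, hi2 = self.hvs2_range
        lo1, hi1 = self.hvs1_range
        return list(range(lo2, hi2 + 1)) + list(range(lo1, hi1 + 1))


def default_reference() -> ReferenceSegments:
    """The package's synthetic default reference (see module docstring)."""
    return ReferenceSegments()
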