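"""From raw control-region reads to normalized haplotypes.

Reads are aligned per segment to the reference with an affine-gap global
aligner, differences are called relative to the reference, and three
normalization rules (all on by default) are applied:

1. variation inside the HVS-II 303-315 poly-C repeat tract is dropped;
2. insertions in the 568-573 poly-C tract collapse to a single C insertion
   (``573insC``);
3. substitution-vs-indel ambiguity inside 16184-16193 resolves to
   substitutions.

The HVS-II "AC" repeat ending at 524 is recorded as unit ``523insCA`` /
``523delCA`` events; copy number beyond one unit collapses to one by
default.  Indels are a fifth character state: one indel event contributes
weight 1 to haplotype identity and to pairwise distances.  Unknown bases
(N) suppress calls at their positions and mark the profile partially
observed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO

from .reference import (
    AMBIGUOUS_16184_16193,
    CA_REPEAT_REGION,
    EXCLUDED_TRACT,
    POLYC_568_573,
    ReferenceSegments,
    default_reference,
)
from .variants import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    Variant,
    variant_key,
)

IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class AlignmentPolicy:
    """Alignment scores and normalization-rule switches."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    min_identity: float = 0.8
    min_coverage: float = 0.8
    drop_303_315: bool = True
    polyc_568_573_rule: bool = True
    resolve_16184_16193: bool = True
    collapse_ca_repeat: bool = True


@dataclass(frozen=True)
class AlignedPair:
    """A gapped (reference, read) pair over one segment."""

    segment: str
    ref_start: int  # rCRS position of the first reference column
    ref_gapped: str
    read_gapped: str

    def __post_init__(self) -> None:
        if len(self.ref_gapped) != len(self.read_gapped):
            raise ValueError("gapped sequences must have equal length")


class UnalignableRead(ValueError):
    """Read rejected: identity or coverage below the policy thresholds."""


def _aligner(policy: AlignmentPolicy) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = policy.match
    a.mismatch_score = policy.mismatch
    a.open_gap_score = policy.gap_open
    a.extend_gap_score = policy.gap_extend
    # reads may cover only part of a segment: end gaps in the read are free
    a.end_deletion_score = 0.0
    return a


def align_to_reference(
    read: str,
    ref: ReferenceSegments | None = None,
    policy: AlignmentPolicy = AlignmentPolicy(),
    segment: str | None = None,
) -> AlignedPair:
    """Align a read to its best-scoring reference segment.

    The segment is auto-detected by alignment score unless given.  Raises
    :class:`UnalignableRead` when identity over aligned columns falls below
    ``policy.min_identity`` or the read covers less than
    ``policy.min_coverage`` of the segment.
    """
    ref = ref or default_reference()
    read = read.strip().upper().replace("U", "T")
    if not read:
        raise UnalignableRead("empty read")
    bad = set(read) - IUPAC
    if bad:
        raise UnalignableRead(f"non-IUPAC characters in read: {sorted(bad)}")

    aligner = _aligner(policy)
    best = None
    for name, (lo, _hi), seq in ref.segments():
        if segment is not None and name != segment:
            continue
        aln = aligner.align(seq, read)[0]
        if best is None or aln.score > best[0]:
            best = (aln.score, name, lo, aln)
    assert best is not None
    _, name, lo, aln = best
    ref_gapped, read_gapped = str(aln[0]), str(aln[1])

    # trim read end-gap overhang columns for identity/coverage accounting
    core = [
        i
        for i, (r, q) in enumerate(zip(ref_gapped, read_gapped))
        if q != "-"
    ]
    if not core:
        raise UnalignableRead("read aligned to nothing")
    first, last = core[0], core[-1]
    span_r = ref_gapped[first : last + 1]
    span_q = read_gapped[first : last + 1]
    matches = sum(1 for r, q in zip(span_r, span_q) if r == q and r != "-")
    aligned_cols = sum(1 for r in span_r if r != "-") or 1
    identity = matches / aligned_cols
    seg_len = len([c for c in ref_gapped if c != "-"])
    coverage = aligned_cols / seg_len
    if identity < policy.min_identity:
        raise UnalignableRead(
            f"identity {identity:.2f} below threshold {policy.min_identity}"
        )
    if coverage < policy.min_coverage:
        raise UnalignableRead(
            f"read covers {coverage:.2f} of segment {name}, "
            f"below {policy.min_coverage}"
        )
    return AlignedPair(name, lo, ref_gapped, read_gapped)


# ---------------------------------------------------------------------------
# variant calling


def _in(pos: int, tract: tuple[int, int]) -> bool:
    return tract[0] <= pos <= tract[1]


def call_variants(
    pair: AlignedPair,
    policy: AlignmentPolicy = AlignmentPolicy(),
    ref: ReferenceSegments | None = None,
) -> tuple[list[Variant], bool]:
    """Call normalized variants from an aligned pair.

    Returns ``(variants, partial)`` where ``partial`` is True when unknown
    bases suppressed any call.  Variants are sorted by position.
    """
    subs: list[Variant] = []
    insertions: list[tuple[int, str]] = []  # (preceding ref pos, bases)
    deletions: list[tuple[int, str]] = []  # (first deleted pos, bases)
    partial = False

    pos = pair.ref_start - 1  # last consumed reference position
    ins_run: list[str] = []
    del_run: list[tuple[int, str]] = []

    def flush_ins() -> None:
        nonlocal ins_run
        if ins_run:
            insertions.append((pos_of_ins, "".join(ins_run)))
            ins_run = []

    def flush_del() -> None:
        nonlocal del_run
        if del_run:
            deletions.append((del_run[0][0], "".join(b for _, b in del_run)))
            del_run = []

    pos_of_ins = pos
    for r, q in zip(pair.ref_gapped, pair.read_gapped):
        if r == "-":
            if q != "-":
                if not ins_run:
                    pos_of_ins = pos
                ins_run.append(q)
            continue
        flush_ins()
        pos += 1
        if q == "-":
            del_run.append((pos, r))
            continue
        flush_del()
        if q == r:
            continue
        if q == "N" or q not in "ACGT":
            partial = True
            continue
        subs.append(Variant(pos, SUBSTITUTION, q))
    flush_ins()
    flush_del()

    # deletions/insertions flanking the read (end gaps) are missing data,
    # not variants: drop indels touching the read's unaligned ends
    read_cols = [i for i, q in enumerate(pair.read_gapped) if q != "-"]
    if read_cols:
        covered_lo = pair.ref_start + sum(
            1 for c in pair.ref_gapped[: read_cols[0]] if c != "-"
        )
        covered_hi = pair.ref_start - 1 + sum(
            1 for c in pair.ref_gapped[: read_cols[-1] + 1] if c != "-"
        )
        deletions = [d for d in deletions if covered_lo <= d[0] <= covered_hi]
        insertions = [i for i in insertions if covered_lo <= i[0] <= covered_hi]

    variants = _normalize(subs, insertions, deletions, policy, ref)
    return sorted(set(variants)), partial


def _shift_right_ins(pos: int, bases: str, ref: ReferenceSegments) -> int:
    """Canonical (rightmost) placement of a homopolymer insertion."""
    if len(set(bases)) != 1:
        return pos
    b = bases[0]
    while True:
        try:
            if ref.base_at(pos + 1) == b:
                pos += 1
                continue
        except ValueError:
            pass
        return pos


def _shift_right_del(pos: int, bases: str, ref: ReferenceSegments) -> int:
    """Canonical (rightmost) placement of a homopolymer deletion."""
    if len(set(bases)) != 1:
        return pos
    b = bases[0]
    width = len(bases)
    while True:
        try:
            if ref.base_at(pos + width) == b:
                pos += 1
                continue
        except ValueError:
            pass
        return pos


def _is_ca_unit(bases: str) -> bool:
    half = len(bases) // 2
    return len(bases) >= 2 and len(bases) % 2 == 0 and (
        bases == "CA" * half or bases == "AC" * half
    )


def _normalize(
    subs: list[Variant],
    insertions: list[tuple[int, str]],
    deletions: list[tuple[int, str]],
    policy: AlignmentPolicy,
    ref: ReferenceSegments | None = None,
) -> list[Variant]:
    ref = ref or default_reference()
    insertions = [(_shift_right_ins(p, b, ref), b) for p, b in insertions]
    deletions = [(_shift_right_del(p, b, ref), b) for p, b in deletions]
    out: list[Variant] = []

    # rule 1: drop the 303-315 repeat tract entirely
    def excluded(pos: int, width: int = 1) -> bool:
        return policy.drop_303_315 and all(
            _in(p, EXCLUDED_TRACT) for p in range(pos, pos + width)
        )

    # rule 3: resolve the 16184-16193 tract to substitutions when the read
    # carries the same number of bases as the reference there
    amb_lo, amb_hi = AMBIGUOUS_16184_16193
    amb_width = amb_hi - amb_lo + 1
    amb_subs = [v for v in subs if _in(v.position, AMBIGUOUS_16184_16193)]
    amb_ins = [i for i in insertions if _in(i[0], AMBIGUOUS_16184_16193)]
    amb_del = [d for d in deletions if _in(d[0], AMBIGUOUS_16184_16193)]
    if policy.resolve_16184_16193 and (amb_ins or amb_del):
        n_read = (
            amb_width
            - sum(len(d[1]) for d in amb_del)
            + sum(len(i[1]) for i in amb_ins)
        )
        if n_read == amb_width:
            # same length: realign gaplessly inside the tract; keep existing
            # substitution calls, convert indel pairs to substitutions at the
            # deleted positions using the inserted bases in order
            ins_bases = "".join(b for _, b in sorted(amb_ins))
            del_positions = sorted(
                p for d in amb_del for p in range(d[0], d[0] + len(d[1]))
            )
            for p, b in zip(del_positions, ins_bases):
                amb_subs.append(Variant(p, SUBSTITUTION, b))
            insertions = [i for i in insertions if i not in amb_ins]
            deletions = [d for d in deletions if d not in amb_del]
            subs = [v for v in subs if not _in(v.position, AMBIGUOUS_16184_16193)]
            subs.extend(amb_subs)

    for v in subs:
        if not excluded(v.position):
            out.append(v)

    # rule 2 + CA-repeat normalization for indels
    polyc_seen = False
    ca_ins = 0
    ca_del = 0
    for pos, bases in insertions:
        if excluded(pos):
            continue
        if policy.polyc_568_573_rule and (
            _in(pos, POLYC_568_573) or pos == POLYC_568_573[0] - 1
        ) and set(bases) == {"C"}:
            polyc_seen = True
            continue
        if policy.collapse_ca_repeat and _is_ca_unit(bases) and _in(
            pos, (CA_REPEAT_REGION[0] - 2, CA_REPEAT_REGION[1] + 1)
        ):
            ca_ins += len(bases) // 2
            continue
        out.append(Variant(pos, INSERTION, bases))
    for pos, bases in deletions:
        if excluded(pos, len(bases)):
            continue
        if policy.collapse_ca_repeat and _is_ca_unit(bases) and _in(
            pos, (CA_REPEAT_REGION[0] - 2, CA_REPEAT_REGION[1] + 1)
        ):
            ca_del += len(bases) // 2
            continue
        out.append(Variant(pos, DELETION, bases))
    if polyc_seen:
        out.append(Variant(573, INSERTION, "C"))
    if ca_ins:
        out.append(Variant(523, INSERTION, "CA"))
    if ca_del:
        out.append(Variant(523, DELETION, "CA"))
    return out


# ---------------------------------------------------------------------------
# synthesis (inverse of calling, used for round-trips and simulation)


def apply_variants(
    variants: Iterable[Variant],
    ref: ReferenceSegments | None = None,
) -> dict[str, str]:
    """Apply a variant set to the reference; returns segment -> sequence."""
    ref = ref or default_reference()
    out: dict[str, str] = {}
    vs = sorted(set(variants), key=lambda v: (v.position, v.kind))
    for name, (lo, hi), seq in ref.segments():
        cols: list[str] = list(seq)
        ins_after: dict[int, str] = {}
        for v in vs:
            if not (lo <= v.position <= hi):
                continue
            i = v.position - lo
            if v.kind == SUBSTITUTION:
                if v.reversion:
                    continue  # reversion restores the reference state
                cols[i] = v.state
            elif v.kind == DELETION:
                for j in range(len(v.state)):
                    if i + j < len(cols):
                        cols[i + j] = ""
            else:
                ins_after[i] = ins_after.get(i, "") + v.state
        pieces = []
        for i, c in enumerate(cols):
            pieces.append(c)
            if i in ins_after:
                pieces.append(ins_after[i])
        out[name] = "".join(pieces)
    return out


# ---------------------------------------------------------------------------
# haplotype collapse


@dataclass(frozen=True)
class HaplotypeProfile:
    """A unique normalized variant set with per-population counts."""

    variants: tuple[Variant, ...]
    counts: Mapping[str, int] = field(default_factory=dict)
    partial: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(sorted(set(self.variants))))
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def key(self) -> tuple[str, ...]:
        return variant_key(self.variants)

    @property
    def id(self) -> str:
        digest = hashlib.sha1(";".join(self.key).encode()).hexdigest()
        return f"H{digest[:10]}"

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def labels(self) -> frozenset[str]:
        return frozenset(self.key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeProfile):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def with_counts(self, counts: Mapping[str, int]) -> "HaplotypeProfile":
        return replace(self, counts=dict(counts))


def collapse_haplotypes(
    samples: Sequence[tuple[str, str, Iterable[Variant]]],
) -> list[HaplotypeProfile]:
    """Collapse (sample_id, population, variants) records into profiles.

    Profiles partition the input; counts sum to the number of samples.
    Output is ordered by the lexicographic variant-set key.  Duplicate
    sample ids are an error.
    """
    seen: set[str] = set()
    table: dict[tuple[str, ...], dict[str, int]] = {}
    keep: dict[tuple[str, ...], tuple[Variant, ...]] = {}
    for sample_id, pop, vs in samples:
        if sample_id in seen:
            raise ValueError(f"duplicate sample id {sample_id!r}")
        seen.add(sample_id)
        vt = tuple(sorted(set(vs)))
        k = variant_key(vt)
        keep.setdefault(k, vt)
        table.setdefault(k, {})
        table[k][pop] = table[k].get(pop, 0) + 1
    return [
        HaplotypeProfile(keep[k], counts=table[k]) for k in sorted(table)
    ]


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def haplotypes_from_sequences(
    sequences: Mapping[str, tuple[str, Sequence[str]]],
    ref: ReferenceSegments | None = None,
    policy: AlignmentPolicy = AlignmentPolicy(),
) -> list[HaplotypeProfile]:
    """Full small pipeline: ``{sample_id: (population, [segment reads])}``
    to collapsed haplotype profiles."""
    ref = ref or default_reference()
    records = []
    for sample_id, (pop, reads) in sequences.items():
        vs: list[Variant] = []
        for read in reads:
            pair = align_to_reference(read, ref, policy)
            called, _partial = call_variants(pair, policy)
            vs.extend(called)
        records.append((sample_id, pop, vs))
    return collapse_haplotypes(records)
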