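"""Motif-based haplogroup classification on a rooted clade tree.

The tree is data-driven: each clade carries a parent and a list of
defining-variant labels.  The default table ships the L0d/L0k topology with
this package's revised motifs (new clades L0d2d, L0dx and L0d3a; 16300G and
523delCA dropped from L0d3; 16239T dropped from L0d1b; 198T dropped from
L0d2a) plus curated, editable placeholders for clades whose control-region
motifs are not part of that revision.

A haplotype is assigned to the deepest clade whose *cumulative* motif path
it matches.  Reversion motifs (``"16274G!"``) fold the path: they remove
the earlier forward variant at the same position, so the expected variant
set of a clade is the path's net difference from the reference.  A clade
may be matched with up to ``tolerance`` expected variants missing; a
reversion is never demanded as positive evidence, but a haplotype that
still carries the pre-reversion state contradicts the path and is scored
as a mismatch.  Length-variant motifs such as ``523insCA`` match on
presence regardless of repeat copy number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequences import HaplotypeProfile
from .variants import Variant, parse_variant_label

ROOT = "ROOT"


@dataclass(frozen=True)
class CladeDefinition:
    name: str
    parent: str
    defining_variants: tuple[str, ...]
    hvs_only: bool = True
    source: str = "curated"


@dataclass
class MotifTree:
    """Rooted clade hierarchy with defining-mutation lists."""

    clades: dict[str, CladeDefinition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, c in self.clades.items():
            if c.parent != ROOT and c.parent not in self.clades:
                raise ValueError(f"clade {name} has unknown parent {c.parent}")
        # reject cycles / unreachable nodes
        for name in self.clades:
            seen = set()
            cur = name
            while cur != ROOT:
                if cur in seen:
                    raise ValueError(f"cycle through clade {cur}")
                seen.add(cur)
                cur = self.clades[cur].parent

    def __contains__(self, name: str) -> bool:
        return name in self.clades

    def __getitem__(self, name: str) -> CladeDefinition:
        return self.clades[name]

    def names(self) -> list[str]:
        return sorted(self.clades)

    def path(self, name: str) -> list[str]:
        """Clade names from the root's child down to ``name``."""
        out = []
        cur = name
        while cur != ROOT:
            out.append(cur)
            cur = self.clades[cur].parent
        return out[::-1]

    def depth(self, name: str) -> int:
        return len(self.path(name))

    def children(self, name: str) -> list[str]:
        return sorted(c for c, d in self.clades.items() if d.parent == name)

    def subtree(self, name: str) -> set[str]:
        out = {name}
        stack = [name]
        while stack:
            for c in self.children(stack.pop()):
                out.add(c)
                stack.append(c)
        return out

    def expected_variants(self, name: str) -> tuple[frozenset[str], frozenset[int]]:
        """Folded cumulative motif path of a clade.

        Returns ``(expected_labels, reverted_positions)``: the variant
        labels a haplotype of this clade is expected to carry relative to
        the reference, and the positions where a back-mutation restored the
        reference state.
        """
        expected: dict[int, str] = {}  # position -> label (for subs)
        other: set[str] = set()  # indel labels
        reverted: set[int] = set()
        for clade in self.path(name):
            for label in self.clades[clade].defining_variants:
                v = parse_variant_label(label)
                if v.kind == "substitution":
                    if v.reversion:
                        expected.pop(v.position, None)
                        reverted.add(v.position)
                    else:
                        expected[v.position] = f"{v.position}{v.state}"
                        reverted.discard(v.position)
                else:
                    other.add(v.label)
        return frozenset(expected.values()) | frozenset(other), frozenset(reverted)


def load_motif_table(path_or_buffer) -> MotifTree:
    df = pd.read_csv(path_or_buffer, sep="\t", comment="#", dtype=str).fillna("")
    clades = {}
    for _, row in df.iterrows():
        motifs = tuple(m for m in row["motifs"].split(";") if m)
        for m in motifs:
            parse_variant_label(m)  # validate
        clades[row["clade"]] = CladeDefinition(
            name=row["clade"],
            parent=row["parent"],
            defining_variants=motifs,
            hvs_only=row.get("hvs_only", "yes") == "yes",
            source=row.get("source", "curated"),
        )
    return MotifTree(clades)


def load_default_tree() -> MotifTree:
    """The shipped L0d/L0k motif tree (see module docstring)."""
    with resources.files("mitopop.data").joinpath("motifs.tsv").open() as fh:
        return load_motif_table(fh)


# ---------------------------------------------------------------------------
# assignment


@dataclass(frozen=True)
class AssignmentResult:
    label: str
    matched: tuple[str, ...]
    missing: tuple[str, ...]
    extra: tuple[str, ...]
    ambiguous: bool
    macro_label: str | None = None


def _has_ca_insertion(labels: frozenset[str]) -> bool:
    # 523insCA matches on presence of a CA-repeat insertion, any copy number
    for lab in labels:
        if "ins" in lab and lab.endswith(("CA", "AC")):
            pos = int(lab.split("ins")[0])
            if 515 <= pos <= 524:
                return True
    return False


def assign(
    profile: HaplotypeProfile | Iterable[Variant],
    tree: MotifTree | None = None,
    macro_label: str | None = None,
    tolerance: int = 1,
) -> AssignmentResult:
    """Assign a haplotype to the deepest matching clade.

    Candidates are clades with at least one matched expected variant and at
    most ``tolerance`` missing; a variant retained at a position the
    clade's path has reverted counts as missing (the haplotype contradicts
    the back-mutation), while the reversion itself is never required as
    positive evidence.  The winner maximizes (matched - missing), ties
    broken by depth; remaining ties are flagged ambiguous (the
    lexicographically first tied clade is reported, never a silently
    broken tie).  ``macro_label`` restricts the search to that clade's
    subtree.
    """
    tree = tree or load_default_tree()
    if not tree.clades:
        raise ValueError("empty motif tree")
    if isinstance(profile, HaplotypeProfile):
        labels = profile.labels()
    else:
        labels = frozenset(v.label for v in profile)
    # substitutions compare without the reversion mark
    plain = frozenset(lab.rstrip("!") for lab in labels)

    names = tree.names()
    if macro_label is not None:
        if macro_label not in tree:
            raise ValueError(f"unknown macro haplogroup {macro_label!r}")
        names = sorted(tree.subtree(macro_label))

    positions = {}
    for lab in plain:
        positions[int(re.match(r"\d+", lab).group())] = lab

    best: list[tuple[int, int, str, tuple, tuple]] = []
    for name in names:
        expected, reverted = tree.expected_variants(name)
        matched, missing = [], []
        for lab in sorted(expected):
            ok = lab in plain or (
                lab == "523insCA" and _has_ca_insertion(plain)
            )
            (matched if ok else missing).append(lab)
        # a variant retained at a reverted position contradicts the path
        for pos in sorted(reverted):
            if pos in positions:
                missing.append(f"{positions[pos]} (expected reverted)")
        if not matched or len(missing) > tolerance:
            continue
        best.append(
            (
                len(matched) - len(missing),
                tree.depth(name),
                name,
                tuple(matched),
                tuple(missing),
            )
        )

    if not best:
        return AssignmentResult(
            "unclassified", (), (), tuple(sorted(plain)), ambiguous=False,
            macro_label=macro_label,
        )
    top_score = max(b[0] for b in best)
    at_score = [b for b in best if b[0] == top_score]
    top_depth = max(b[1] for b in at_score)
    winners = sorted(b for b in at_score if b[1] == top_depth)
    _score, _depth, name, matched, missing = winners[0]
    ambiguous = len(winners) > 1
    extra = tuple(sorted(plain - set(matched)))
    return AssignmentResult(
        name, matched, missing, extra, ambiguous=ambiguous, macro_label=macro_label
    )


def macro_from_snp_calls(
    snp_calls: Mapping[str, str],
    snp_table: Mapping[str, str],
) -> str | None:
    """Map a sample's coding-region SNP calls to a macro-haplogroup label.

    ``snp_calls`` maps SNP id -> observed allele; ``snp_table`` maps
    "snp_id=allele" strings to macro labels.  Returns the first (unique)
    macro implied, or None.
    """
    hits = {
        macro
        for key, macro in snp_table.items()
        for snp, allele in snp_calls.items()
        if key == f"{snp}={allele}"
    }
    if len(hits) == 1:
        return hits.pop()
    return None


# ---------------------------------------------------------------------------
# frequency tables


def frequency_table(
    assignments: Sequence[tuple[str, str]],
    populations: Sequence[str],
) -> pd.DataFrame:
    """Per-population haplogroup frequency matrix from
    ``(population, haplogroup)`` records.  Rows sum to 1."""
    pops = list(populations)
    for pop, _ in assignments:
        if pop not in pops:
            raise ValueError(f"unknown population code {pop!r}")
    counts = (
        pd.DataFrame(assignments, columns=["population", "haplogroup"])
        .value_counts()
        .unstack(fill_value=0)
    )
    counts = counts.reindex(pops, fill_value=0)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"populations with no assigned samples: {empty}")
    return counts.div(totals, axis=0)
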