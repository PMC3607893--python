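"""Founder-age (rho statistic) dating on a rooted mutation genealogy.

rho is the multiplicity-weighted mean number of mutations separating a
clade's root from its sampled haplotypes; with a per-mutation calibration
it estimates the clade's age.  Its error follows Saillard's recursion:

    sigma^2 = sum over edges of (n_e / n)^2 * m_e

where n_e is the number of sampled lineages below the edge, n the total
sample size and m_e the edge's mutation count (for a star genealogy this
reduces to sqrt(sum m_i)/n).  Coalescence mode roots at the clade MRCA;
divergence mode roots at the MRCA's parent, adding the stem mutations to
every root-to-tip path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

import networkx as nx

from .calibration import DEFAULT_CALIBRATION, RateCalibration


@dataclass(frozen=True)
class RhoEstimate:
    rho: float
    sigma: float
    years: int
    sd_years: int
    mode: str = "coalescence"


class RootedGenealogy:
    """A rooted genealogy with per-edge mutation counts and tip counts.

    Thin wrapper over a networkx DiGraph (edges parent -> child with an
    integer ``mutations`` attribute; nodes may carry a ``count`` attribute
    giving sampled multiplicity — unset leaf nodes default to 1, unset
    internal nodes to 0, so inferred ancestors do not contribute).
    """

    def __init__(self, graph: nx.DiGraph, root: Hashable):
        if root not in graph:
            raise ValueError("root not in genealogy")
        roots = [v for v in graph if graph.in_degree(v) == 0]
        if roots != [root] and (len(roots) != 1 or roots[0] != root):
            raise ValueError("genealogy must have exactly one root")
        for u, v, d in graph.edges(data=True):
            m = d.get("mutations", 0)
            if m < 0 or int(m) != m:
                raise ValueError(f"edge {u}->{v} has invalid mutation count {m}")
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("genealogy must be acyclic")
        self.graph = graph
        self.root = root

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Hashable, Hashable, int]],
        root: Hashable,
        counts: dict | None = None,
    ) -> "RootedGenealogy":
        g = nx.DiGraph()
        g.add_node(root)
        for u, v, m in edges:
            g.add_edge(u, v, mutations=int(m))
        for node, c in (counts or {}).items():
            g.nodes[node]["count"] = int(c)
        return cls(g, root)

    def count(self, node: Hashable) -> int:
        data = self.graph.nodes[node]
        if "count" in data:
            return int(data["count"])
        return 1 if self.graph.out_degree(node) == 0 else 0

    def sampled_below(self, node: Hashable) -> int:
        total = self.count(node)
        for child in self.graph.successors(node):
            total += self.sampled_below(child)
        return total

    def mutations_from(self, src: Hashable) -> dict[Hashable, int]:
        """Mutation distance from src to every descendant."""
        dist = {src: 0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v in self.graph.successors(u):
                dist[v] = dist[u] + self.graph.edges[u, v]["mutations"]
                stack.append(v)
        return dist


def rho(genealogy: RootedGenealogy, clade_root: Hashable | None = None) -> float:
    """Multiplicity-weighted mean mutations from the clade root to tips."""
    src = clade_root if clade_root is not None else genealogy.root
    dist = genealogy.mutations_from(src)
    num = den = 0.0
    for node, d in dist.items():
        c = genealogy.count(node)
        num += c * d
        den += c
    if den == 0:
        raise ValueError("no sampled tips below the clade root")
    return num / den


def sigma_saillard(
    genealogy: RootedGenealogy, clade_root: Hashable | None = None
) -> float:
    src = clade_root if clade_root is not None else genealogy.root
    n = genealogy.sampled_below(src)
    if n == 0:
        raise ValueError("no sampled tips below the clade root")
    var = 0.0
    stack = [src]
    while stack:
        u = stack.pop()
        for v in genealogy.graph.successors(u):
            n_e = genealogy.sampled_below(v)
            m_e = genealogy.graph.edges[u, v]["mutations"]
            var += (n_e / n) ** 2 * m_e
            stack.append(v)
    return var**0.5


def to_years(
    rho_value: float,
    sigma_value: float,
    cal: RateCalibration = DEFAULT_CALIBRATION,
    mode: str = "coalescence",
) -> RhoEstimate:
    """Convert (rho, sigma) to calendar years with the rate calibration."""
    if rho_value < 0 or sigma_value < 0:
        raise ValueError("rho and sigma must be non-negative")
    ypm = cal.years_per_mutation
    return RhoEstimate(
        rho=rho_value,
        sigma=sigma_value,
        years=int(round(rho_value * ypm)),
        sd_years=int(round(sigma_value * ypm)),
        mode=mode,
    )


def divergence_vs_coalescence(
    genealogy: RootedGenealogy,
    clade_root: Hashable,
    cal: RateCalibration = DEFAULT_CALIBRATION,
) -> tuple[RhoEstimate, RhoEstimate]:
    """(divergence, coalescence) estimates for a clade.

    Coalescence roots at the clade MRCA; divergence roots at its parent
    node (where the clade split from the other lineages), which adds the
    stem mutations to every tip path and the full stem weight to sigma^2.
    """
    parents = list(genealogy.graph.predecessors(clade_root))
    if not parents:
        raise ValueError("clade root is the global root: divergence undefined")
    parent = parents[0]
    stem = genealogy.graph.edges[parent, clade_root]["mutations"]

    r_coal = rho(genealogy, clade_root)
    s_coal = sigma_saillard(genealogy, clade_root)
    # divergence over the same tip set: every path gains the stem mutations
    r_div = r_coal + stem
    s_div = (s_coal**2 + stem) ** 0.5
    return (
        to_years(r_div, s_div, cal, mode="divergence"),
        to_years(r_coal, s_coal, cal, mode="coalescence"),
    )
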