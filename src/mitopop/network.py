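"""Median-joining haplotype networks.

Haplotypes are binary vectors of variant presence/absence (indels are a
fifth state with weight 1, positions may carry weights).  The network is
built by the median-joining procedure: build the epsilon-relaxed minimum
spanning network (the union of all minimum spanning trees, plus links
within epsilon of feasibility), add the consensus (quasi-median) vector of
triplets that are mutually linked, and repeat until no new median arises;
obsolete median vectors (degree <= 2 shortcuts) are pruned.  Output is
deterministic: ties break on the lexicographic haplotype key everywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .distances import weighted_distance
from .sequences import HaplotypeProfile

MAX_MEDIANS = 10_000


@dataclass(frozen=True)
class NetworkParams:
    epsilon: float = 0.0
    weights: Mapping[int, float] | None = None
    max_medians: int = MAX_MEDIANS

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


def node_key(labels: frozenset[str]) -> str:
    return ";".join(sorted(labels))


def _distance_pairs(nodes: Sequence[frozenset[str]], weights):
    d = {}
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            d[(i, j)] = weighted_distance(a, b=nodes[j], weights=weights)
    return d


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def minimum_spanning_network(
    nodes: Sequence[frozenset[str]],
    weights=None,
    epsilon: float = 0.0,
) -> list[tuple[int, int, float]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    A pair joins the network when its distance is within epsilon of the
    distance level at which its endpoints first become connected by
    shorter links (epsilon = 0 gives exactly the union of all minimum
    spanning trees).
    """
    dist = _distance_pairs(nodes, weights)
    levels = sorted(set(dist.values()))
    uf = _UnionFind(len(nodes))
    # mu[(i, j)] = Kruskal merge level: the smallest distance level at which
    # i and j are connected (the minimax path distance); d >= mu always
    mu: dict[tuple[int, int], float] = {}
    for level in levels:
        for (i, j), d in sorted(dist.items()):
            if d == level:
                uf.union(i, j)
        for (i, j), _ in sorted(dist.items()):
            if (i, j) not in mu and uf.find(i) == uf.find(j):
                mu[(i, j)] = level
    return [
        (i, j, d)
        for (i, j), d in sorted(dist.items())
        if d <= mu[(i, j)] + epsilon
    ]


def _consensus_median(
    a: frozenset[str], b: frozenset[str], c: frozenset[str]
) -> frozenset[str]:
    """Majority-state (quasi-median) vector of three haplotypes."""
    union = a | b | c
    return frozenset(
        lab for lab in union if (lab in a) + (lab in b) + (lab in c) >= 2
    )


def median_joining(
    profiles: Sequence[HaplotypeProfile] | Sequence[frozenset[str]],
    params: NetworkParams = NetworkParams(),
) -> nx.Graph:
    """Median-joining network of the given haplotypes.

    Returns an undirected graph whose nodes are haplotype keys with
    attributes ``labels`` (frozenset), ``median`` (bool), ``count`` and
    ``populations``; edges carry ``weight`` and ``diff`` (the variant
    labels separating the endpoints).
    """
    meta: dict[frozenset[str], dict] = {}
    for p in profiles:
        labels = p.labels() if isinstance(p, HaplotypeProfile) else frozenset(p)
        entry = meta.setdefault(labels, {"count": 0, "populations": {}})
        if isinstance(p, HaplotypeProfile):
            entry["count"] += p.n
            for pop, c in p.counts.items():
                entry["populations"][pop] = entry["populations"].get(pop, 0) + c
        else:
            entry["count"] += 1
    if not meta:
        raise ValueError("median_joining needs at least one haplotype")

    observed = sorted(meta, key=node_key)
    nodes: list[frozenset[str]] = list(observed)
    node_set = set(nodes)

    while True:
        edges = minimum_spanning_network(nodes, params.weights, params.epsilon)
        linked = {(i, j) for i, j, _ in edges}
        new: set[frozenset[str]] = set()
        for i, j, k in itertools.combinations(range(len(nodes)), 3):
            pairs = [(i, j), (i, k), (j, k)]
            n_linked = sum(1 for p in pairs if p in linked)
            if n_linked < 2:
                continue
            med = _consensus_median(nodes[i], nodes[j], nodes[k])
            if med not in node_set and med not in new:
                new.add(med)
        if not new or len(nodes) + len(new) > params.max_medians:
            break
        for med in sorted(new, key=node_key):
            nodes.append(med)
            node_set.add(med)
        nodes = sorted(node_set, key=node_key)

    # prune obsolete median vectors: unsampled nodes of degree <= 2
    while True:
        edges = minimum_spanning_network(nodes, params.weights, params.epsilon)
        degree = {i: 0 for i in range(len(nodes))}
        for i, j, _ in edges:
            degree[i] += 1
            degree[j] += 1
        drop = [
            nodes[i]
            for i in range(len(nodes))
            if nodes[i] not in meta and degree[i] <= 2
        ]
        if not drop:
            break
        node_set -= set(drop)
        nodes = sorted(node_set, key=node_key)

    g = nx.Graph()
    for labels in nodes:
        entry = meta.get(labels, {"count": 0, "populations": {}})
        g.add_node(
            node_key(labels),
            labels=labels,
            median=labels not in meta,
            count=entry["count"],
            populations=dict(entry["populations"]),
        )
    for i, j, d in minimum_spanning_network(nodes, params.weights, params.epsilon):
        a, b = nodes[i], nodes[j]
        g.add_edge(
            node_key(a),
            node_key(b),
            weight=d,
            diff=tuple(sorted(a ^ b)),
        )
    return g


# ---------------------------------------------------------------------------
# rooting and summaries


@dataclass(frozen=True)
class RootedNetwork:
    graph: nx.Graph
    root: str
    orientation: Mapping[tuple[str, str], str] = field(default_factory=dict)
    ambiguous_edges: frozenset[frozenset[str]] = frozenset()


def root_with_outgroup(
    graph: nx.Graph,
    outgroup: HaplotypeProfile | Iterable[str],
) -> RootedNetwork:
    """Root the network at the node nearest the outgroup.

    Edges on cycles cannot be oriented and are flagged ambiguous; all
    other edges are oriented away from the root.
    """
    og = (
        outgroup.labels()
        if isinstance(outgroup, HaplotypeProfile)
        else frozenset(outgroup)
    )
    best = min(
        graph.nodes,
        key=lambda nk: (weighted_distance(graph.nodes[nk]["labels"], og), nk),
    )
    cyc_edges: set[frozenset[str]] = set()
    for cycle in nx.cycle_basis(graph):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            cyc_edges.add(frozenset((a, b)))
    orientation: dict[tuple[str, str], str] = {}
    for parent, child in nx.bfs_edges(graph, best, sort_neighbors=sorted):
        if frozenset((parent, child)) not in cyc_edges:
            orientation[(parent, child)] = "away-from-root"
    return RootedNetwork(
        graph=graph,
        root=best,
        orientation=orientation,
        ambiguous_edges=frozenset(cyc_edges),
    )


@dataclass(frozen=True)
class StarPattern:
    center: str
    leaves: tuple[str, ...]
    populations: Mapping[str, int]


def star_contraction_summary(
    graph: nx.Graph, min_leaves: int = 4
) -> list[StarPattern]:
    """Star-like expansion patterns: nodes with >= min_leaves leaf
    neighbors, with the populations represented across the star."""
    out = []
    for center in sorted(graph.nodes):
        leaves = tuple(
            sorted(v for v in graph.neighbors(center) if graph.degree(v) == 1)
        )
        if len(leaves) >= min_leaves:
            pops: dict[str, int] = {}
            for node in (center, *leaves):
                for pop, c in graph.nodes[node].get("populations", {}).items():
                    pops[pop] = pops.get(pop, 0) + c
            out.append(StarPattern(center, leaves, pops))
    return out


def to_genealogy(rooted: RootedNetwork):
    """Resolve a rooted network to a spanning-tree genealogy for rho dating.

    The resolution is the BFS shortest-path tree from the root with
    lexicographic tie-breaks; edge mutation counts are the unweighted
    variant differences.  Reticulations are resolved, not averaged —
    callers should report this resolution alongside estimates.
    """
    from .rho import RootedGenealogy

    g = nx.DiGraph()
    graph = rooted.graph
    g.add_node(rooted.root, count=graph.nodes[rooted.root].get("count", 0))
    for parent, child in nx.bfs_edges(graph, rooted.root, sort_neighbors=sorted):
        diff = graph.edges[parent, child]["diff"]
        g.add_edge(parent, child, mutations=len(diff))
        g.nodes[child]["count"] = graph.nodes[child].get("count", 0)
    return RootedGenealogy(g, rooted.root)
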