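"""Median-joining network construction, rooting and star summaries."""

import itertools

import pytest

from mitopop import (
    HaplotypeProfile,
    median_joining,
    root_with_outgroup,
    star_contraction_summary,
    to_genealogy,
    weighted_distance,
)
from mitopop.network import (
    NetworkParams,
    minimum_spanning_network,
    node_key,
)
from mitopop.variants import parse_variant_label as pv

A, B, C = "100T", "200C", "300G"


class TestWeightedDistance:
    def test_identity(self):
        assert weighted_distance(frozenset({A}), frozenset({A})) == 0.0

    def test_unit_weights(self):
        assert weighted_distance(frozenset({A}), frozenset({B})) == 2.0

    def test_downweighted_position(self):
        d = weighted_distance(
            frozenset({"16189C"}), frozenset(), weights={16189: 0.5}
        )
        assert d == 0.5

    def test_triangle_inequality(self):
        xs = [frozenset(), frozenset({A}), frozenset({A, B}), frozenset({B, C})]
        for x, y, z in itertools.permutations(xs, 3):
            assert weighted_distance(x, z) <= weighted_distance(
                x, y
            ) + weighted_distance(y, z)


def _mst_weight(nodes):
    """Minimum spanning tree weight by exhaustive Prüfer enumeration."""
    n = len(nodes)
    if n == 2:
        return weighted_distance(nodes[0], nodes[1])
    best = float("inf")
    for pruefer in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in pruefer:
            degree[v] += 1
        seq = list(pruefer)
        leaves = sorted(i for i in range(n) if degree[i] == 1)
        edges = []
        seq_i = 0
        deg = degree[:]
        avail = leaves[:]
        for v in seq:
            leaf = avail.pop(0)
            edges.append((leaf, v))
            deg[v] -= 1
            if deg[v] == 1:
                import bisect

                bisect.insort(avail, v)
        edges.append((avail[0], avail[1]))
        w = sum(weighted_distance(nodes[u], nodes[v]) for u, v in edges)
        best = min(best, w)
    return best


class TestMedianJoining:
    def test_two_profiles_single_edge(self):
        g = median_joining([frozenset({A}), frozenset({B})])
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_triplet_steiner_point(self):
        """The 110/011/101 pattern gets exactly one median (the consensus)
        and three unit edges — verified against exhaustive Steiner search
        over all 2^3 candidate haplotypes on these positions."""
        profs = [frozenset({A, B}), frozenset({B, C}), frozenset({A, C})]
        g = median_joining(profs)
        medians = [n for n, d in g.nodes(data=True) if d["median"]]
        assert medians == [node_key(frozenset({A, B, C}))]
        assert sorted(d["weight"] for _, _, d in g.edges(data=True)) == [
            1.0,
            1.0,
            1.0,
        ]
        # exhaustive: adding any single candidate node, 3 is the best cost
        labels = [A, B, C]
        best = float("inf")
        for r in range(4):
            for combo in itertools.combinations(labels, r):
                cand = frozenset(combo)
                cost = sum(weighted_distance(cand, p) for p in profs)
                best = min(best, cost)
        total = sum(d["weight"] for _, _, d in g.edges(data=True))
        assert total == best == 3.0

    def test_medians_cannot_increase_connecting_cost(self):
        """The spanning cost of the network's node set (observed plus
        medians) never exceeds the MST weight of the observed profiles."""
        import networkx as nx

        profs = [
            frozenset(),
            frozenset({A}),
            frozenset({A, B}),
            frozenset({B, C}),
            frozenset({A, C}),
        ]
        g = median_joining(profs)
        medians = [
            d["labels"] for _, d in g.nodes(data=True) if d["median"]
        ]

        def mst_over(nodes):
            k = nx.complete_graph(len(nodes))
            for u, v in k.edges:
                k.edges[u, v]["weight"] = weighted_distance(
                    nodes[u], nodes[v]
                )
            return nx.minimum_spanning_tree(k).size(weight="weight")

        best = min(
            mst_over(profs + list(sub))
            for r in range(len(medians) + 1)
            for sub in itertools.combinations(medians, r)
        )
        assert best <= _mst_weight(profs) + 1e-9

    def test_epsilon_zero_equals_union_of_msts(self):
        """With no medians addable, the epsilon=0 network over observed
        nodes equals the union of all minimum spanning trees (exhaustive
        spanning-tree enumeration oracle)."""
        profs = [
            frozenset(),
            frozenset({A}),
            frozenset({B}),
            frozenset({A, B, C}),
        ]
        edges = minimum_spanning_network(profs, epsilon=0.0)
        got = {(i, j) for i, j, _ in edges}
        # oracle: enumerate all labeled spanning trees, keep minimal ones
        n = len(profs)
        best_w = float("inf")
        trees = []
        for pruefer in itertools.product(range(n), repeat=n - 2):
            import networkx as nx

            t = nx.from_prufer_sequence(list(pruefer))
            w = sum(
                weighted_distance(profs[u], profs[v]) for u, v in t.edges
            )
            if w < best_w - 1e-12:
                best_w, trees = w, [t]
            elif abs(w - best_w) < 1e-12:
                trees.append(t)
        union = {
            (min(u, v), max(u, v)) for t in trees for u, v in t.edges
        }
        assert got == union

    def test_all_observed_haplotypes_present_with_counts(self):
        profs = [
            HaplotypeProfile((pv(A),), {"X": 3}),
            HaplotypeProfile((pv(A), pv(B)), {"Y": 2}),
        ]
        g = median_joining(profs)
        counts = {
            n: d["count"] for n, d in g.nodes(data=True) if not d["median"]
        }
        assert sum(counts.values()) == 5

    def test_stable_under_input_permutation(self):
        profs = [
            frozenset(),
            frozenset({A}),
            frozenset({A, B}),
            frozenset({B, C}),
        ]
        g1 = median_joining(profs)
        g2 = median_joining(profs[::-1])
        assert sorted(g1.nodes) == sorted(g2.nodes)
        assert sorted(map(sorted, g1.edges)) == sorted(map(sorted, g2.edges))

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(epsilon=-1)


class TestRooting:
    def test_chain_oriented_away_from_outgroup(self):
        chain = [frozenset(), frozenset({A}), frozenset({A, B})]
        g = median_joining(chain)
        rooted = root_with_outgroup(g, frozenset({"999T"}))
        assert rooted.root == node_key(frozenset())
        assert all(v == "away-from-root" for v in rooted.orientation.values())
        assert not rooted.ambiguous_edges

    def test_reticulation_flagged_ambiguous(self):
        square = [
            frozenset(),
            frozenset({A}),
            frozenset({B}),
            frozenset({A, B}),
        ]
        g = median_joining(square)
        rooted = root_with_outgroup(g, frozenset())
        assert len(rooted.ambiguous_edges) >= 3  # the 4-cycle

    def test_planted_clade_ancestor_identified(self, tree):
        anc, _ = tree.expected_variants("L0d1")
        tips = [anc | {f"1650{i}T"} for i in range(2)]
        g = median_joining([frozenset(anc), *map(frozenset, tips)])
        rooted = root_with_outgroup(g, frozenset())
        assert rooted.root == node_key(frozenset(anc))


class TestStarSummary:
    def test_perfect_star(self):
        profs = [frozenset({A})] + [
            frozenset({A, f"{400 + i}T"}) for i in range(5)
        ]
        g = median_joining(profs)
        patterns = star_contraction_summary(g)
        assert len(patterns) == 1 and len(patterns[0].leaves) == 5

    def test_chain_has_none(self):
        chain = [frozenset(), frozenset({A}), frozenset({A, B})]
        g = median_joining(chain)
        assert star_contraction_summary(g) == []


class TestGenealogyResolution:
    def test_rho_on_resolved_chain(self):
        chain = [frozenset(), frozenset({A}), frozenset({A, B})]
        g = median_joining(chain)
        rooted = root_with_outgroup(g, frozenset({"999T"}))
        from mitopop import rho

        genealogy = to_genealogy(rooted)
        assert rho(genealogy) == pytest.approx(1.0)
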