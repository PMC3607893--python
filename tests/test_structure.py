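"""PhiST, UPGMA, geographic distance, Mantel and frequency surfaces."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mitopop import (
    PopulationSample,
    distance_regression,
    frequency_surface,
    geographic_matrix,
    great_circle_km,
    mantel,
    pairwise_fst,
    upgma,
)
from mitopop.structure import phi_st_pair


def _d2_table(table):
    def d2(h, g):
        if h == g:
            return 0.0
        return table.get((h, g), table.get((g, h)))

    return d2


class TestPhiST:
    def test_identical_distributions_no_differentiation(self):
        a = PopulationSample("A", {"h1": 5, "h2": 5})
        b = PopulationSample("B", {"h1": 5, "h2": 5})
        d2 = _d2_table({("h1", "h2"): 1.0})
        assert phi_st_pair(a, b, d2) <= 0.0

    def test_fixed_different_haplotypes_is_one(self):
        a = PopulationSample("A", {"h1": 10})
        b = PopulationSample("B", {"h2": 10})
        d2 = _d2_table({("h1", "h2"): 4.0})
        assert phi_st_pair(a, b, d2) == pytest.approx(1.0)

    def test_hand_computed_variance_components(self):
        """Two-population toy against a by-hand AMOVA decomposition."""
        a = PopulationSample("A", {"h1": 3, "h2": 1})
        b = PopulationSample("B", {"h1": 1, "h3": 3})
        d2 = _d2_table({("h1", "h2"): 1.0, ("h1", "h3"): 2.0, ("h2", "h3"): 3.0})
        hap = ["h1"] * 3 + ["h2"] + ["h1"] + ["h3"] * 3
        N = 8
        ss_total = (
            sum(
                d2(hap[i], hap[j])
                for i in range(N)
                for j in range(i + 1, N)
            )
            / N
        )
        ss_within = (
            sum(d2(x, y) for x, y in itertools.combinations(hap[:4], 2)) / 4
            + sum(d2(x, y) for x, y in itertools.combinations(hap[4:], 2)) / 4
        )
        ms_within = ss_within / (N - 2)
        n_prime = (N - (16 + 16) / N) / 1
        sigma2_a = ((ss_total - ss_within) - ms_within) / n_prime
        expected = sigma2_a / (sigma2_a + ms_within)
        assert phi_st_pair(a, b, d2) == pytest.approx(expected, abs=1e-10)

    def test_matrix_symmetric_and_order_invariant(self):
        pops = [
            PopulationSample("A", {frozenset({"100T"}): 12}),
            PopulationSample("B", {frozenset({"200C"}): 11}),
            PopulationSample("C", {frozenset(): 10}),
        ]
        m1 = pairwise_fst(pops)
        m2 = pairwise_fst(pops[::-1])
        for x, y in itertools.combinations("ABC", 2):
            assert m1.loc[x, y] == m1.loc[y, x]
            assert m1.loc[x, y] == pytest.approx(m2.loc[x, y])

    def test_small_groups_excluded_by_default(self):
        pops = [
            PopulationSample("A", {frozenset({"100T"}): 12}),
            PopulationSample("B", {frozenset({"200C"}): 11}),
            PopulationSample("TINY", {frozenset(): 3}),
        ]
        m = pairwise_fst(pops)
        assert list(m.index) == ["A", "B"]
        m2 = pairwise_fst(pops, include_small=True)
        assert "TINY" in m2.index

    def test_frequency_mode(self):
        a = PopulationSample("A", {"h1": 10})
        b = PopulationSample("B", {"h2": 10})
        m = pairwise_fst([a, b], mode="frequency")
        assert m.loc["A", "B"] == pytest.approx(1.0)


class TestUPGMA:
    def test_two_population_cherry(self):
        m = pd.DataFrame(
            [[0.0, 3.0], [3.0, 0.0]], index=["A", "B"], columns=["A", "B"]
        )
        t = upgma(m)
        tips = {tip.name: tip.length for tip in t.tips()}
        assert tips == {"A": pytest.approx(1.5), "B": pytest.approx(1.5)}

    def test_three_taxon_hand_computation(self):
        # d(AB)=2, d(AC)=8, d(BC)=6: (A,B) at height 1, C joins at 3.5
        m = pd.DataFrame(
            [[0, 2, 8], [2, 0, 6], [8, 6, 0]],
            index=list("ABC"),
            columns=list("ABC"),
            dtype=float,
        )
        t = upgma(m)
        assert str(t).strip() == "(C:3.5,(A:1.0,B:1.0):2.5);"

    def test_negative_distances_clamped_with_warning(self):
        m = pd.DataFrame(
            [[0, -0.02], [-0.02, 0]], index=["A", "B"], columns=["A", "B"],
            dtype=float,
        )
        with pytest.warns(UserWarning, match="clamped"):
            t = upgma(m)
        assert {tip.name for tip in t.tips()} == {"A", "B"}

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            upgma(pd.DataFrame([[0.0, 1.0]], index=["A"], columns=["A", "B"]))

    def test_planted_clusters_separate(self):
        labels = ["N1", "N2", "N3", "S1", "S2", "S3"]
        m = pd.DataFrame(0.1, index=labels, columns=labels)
        for x in labels:
            for y in labels:
                if x[0] != y[0]:
                    m.loc[x, y] = 0.8
        np.fill_diagonal(m.values, 0.0)
        t = upgma(m)
        # the root's two children split exactly north / south
        sides = [
            {tip.name[0] for tip in child.tips()} or {child.name[0]}
            for child in t.children
        ]
        assert sorted(map(sorted, sides)) == [["N"], ["S"]]


class TestGeography:
    def test_zero_distance(self):
        assert great_circle_km((10, 20), (10, 20)) == 0.0

    def test_antipodal(self):
        assert great_circle_km((0, 0), (0, 180)) == pytest.approx(
            math.pi * 6371.0
        )

    def test_one_degree_longitude_on_equator(self):
        assert great_circle_km((0, 0), (0, 1)) == pytest.approx(
            6371.0 * math.pi / 180, abs=1e-6
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_km((95, 0), (0, 0))


class TestMantel:
    def _pair(self):
        rng = np.random.default_rng(0)
        x = np.array(
            [[0, 1, 2, 3], [1, 0, 1.5, 2.5], [2, 1.5, 0, 1.2], [3, 2.5, 1.2, 0]]
        )
        noise = rng.normal(0, 0.3, (4, 4))
        y = x + (noise + noise.T) / 2
        np.fill_diagonal(y, 0)
        idx = list("abcd")
        return (
            pd.DataFrame(x, index=idx, columns=idx),
            pd.DataFrame(y, index=idx, columns=idx),
        )

    def test_self_correlation_is_one(self):
        gx, _ = self._pair()
        res = mantel(gx, gx, n_permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_exact_enumeration_matches_independent_oracle(self):
        from scipy.stats import pearsonr

        gx, gy = self._pair()
        res = mantel(gx, gy, method="exact")
        x, y = gx.to_numpy(), gy.to_numpy()
        iu = np.triu_indices(4, k=1)
        r_obs = pearsonr(x[iu], y[iu])[0]
        hits = sum(
            pearsonr(x[iu], y[np.ix_(p, p)][iu])[0] >= r_obs - 1e-12
            for p in itertools.permutations(range(4))
        )
        assert res.p == pytest.approx(hits / 24)
        assert res.n_permutations == 24

    def test_zero_variance_rejected(self):
        idx = list("abc")
        flat = pd.DataFrame(1.0, index=idx, columns=idx)
        np.fill_diagonal(flat.values, 0.0)
        other = flat.copy()
        other.iloc[0, 1] = other.iloc[1, 0] = 2.0
        with pytest.raises(ValueError):
            mantel(flat, other, n_permutations=9)

    def test_permutation_seeded(self):
        gx, gy = self._pair()
        a = mantel(gx, gy, n_permutations=199, seed=3)
        b = mantel(gx, gy, n_permutations=199, seed=3)
        assert a.p == b.p


class TestRegression:
    def test_monotone_relation_positive_slope(self):
        rng = np.random.default_rng(2)
        pops = [
            PopulationSample(f"P{i}", {"h": 10}, lat=-20 - 2.5 * i, lon=20)
            for i in range(6)
        ]
        geo = geographic_matrix(pops)
        gen = geo * 1e-4 + rng.normal(0, 0.01, geo.shape)
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen.values, 0)
        slope, _, p = distance_regression(gen, geo)
        assert slope > 0 and p < 0.05


class TestFrequencySurface:
    def _pops(self):
        return [
            PopulationSample("N", {"h": 10}, lat=-18.0, lon=22.0),
            PopulationSample("S", {"h": 10}, lat=-33.0, lon=20.0),
        ]

    def test_exact_at_sample_points(self):
        pops = self._pops()
        lats, lons, surf = frequency_surface(
            pops, {"N": 0.75, "S": 0.25}, grid=(-33.0, -18.0, 20.0, 22.0),
            n_cells=16,
        )
        i_n = int(np.argmin(np.abs(lats - -18.0)))
        j_n = int(np.argmin(np.abs(lons - 22.0)))
        assert surf[i_n, j_n] == pytest.approx(0.75)

    def test_north_loaded_frequencies_peak_north(self):
        pops = self._pops()
        lats, lons, surf = frequency_surface(
            pops, {"N": 0.9, "S": 0.1}, grid=(-34.0, -17.0, 19.0, 23.0),
            n_cells=20,
        )
        north_half = surf[lats > -25.5, :].mean()
        south_half = surf[lats <= -25.5, :].mean()
        assert north_half > south_half
        assert surf.min() >= 0.0 and surf.max() <= 1.0
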