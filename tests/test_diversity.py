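"""Diversity estimators and neutrality statistics against independent oracles."""

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest

from mitopop import (
    HaplotypeProfile,
    effective_size,
    fu_fs,
    haplotype_diversity,
    mean_pairwise_differences,
    nucleotide_diversity,
    r2_statistic,
    tajimas_d,
    watterson_theta,
)
from mitopop.diversity import (
    ewens_log_pmf,
    neutrality_pvalues,
    segregating_labels,
    singletons_per_sequence,
    summarize,
)
from mitopop.variants import parse_variant_label as pv


def _profiles(spec):
    """spec: list of (labels, count) -> HaplotypeProfiles in one population."""
    return [
        HaplotypeProfile(tuple(pv(x) for x in labels), {"X": c})
        for labels, c in spec
    ]


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts, expected",
        [((2, 1), 0.667), ((2, 1, 1), 0.833), ((2, 2, 1, 1), 0.867)],
    )
    def test_printed_partitions(self, counts, expected):
        assert round(haplotype_diversity(counts), 3) == expected

    def test_all_distinct_is_one(self):
        assert haplotype_diversity([1] * 7) == pytest.approx(1.0)

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            haplotype_diversity([1])

    def test_invariant_under_relabeling(self):
        assert haplotype_diversity([3, 2, 1]) == haplotype_diversity([1, 3, 2])


class TestWattersonTheta:
    @pytest.mark.parametrize(
        "S, n, expected", [(5, 21, 1.390), (4, 31, 1.001), (0, 10, 0.0)]
    )
    def test_printed_values(self, S, n, expected):
        theta_locus, _ = watterson_theta(S, n)
        assert round(theta_locus, 3) == expected

    def test_matches_direct_summation(self):
        for S, n in [(13, 37), (2, 5), (40, 200)]:
            theta_locus, theta_site = watterson_theta(S, n, L=1124)
            a1 = sum(1.0 / i for i in range(1, n))
            assert abs(theta_locus - S / a1) < 1e-12
            assert abs(theta_site - S / a1 / 1124) < 1e-15


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        profs = _profiles([(("16223T",), 2)])
        assert nucleotide_diversity(profs, 1124) == 0.0

    def test_enumeration_example(self):
        # counts (2,1), 6 sites apart: pairs (a,a)=0, (a,b)x2=6 -> mean 4
        six = ("100T", "200C", "300G", "16400T", "16401T", "16402C")
        profs = _profiles([((), 2), (six, 1)])
        assert mean_pairwise_differences(profs) == pytest.approx(4.0)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        labels = [f"{100 + i}T" for i in range(30)]
        profs = []
        for c in (3, 2, 1, 1, 4):
            chosen = rng.choice(labels, size=rng.integers(0, 10), replace=False)
            profs.append(
                HaplotypeProfile(tuple(pv(x) for x in chosen), {"X": int(c)})
            )
        # brute force: expand to individual sequences, O(n^2) loop
        seqs = []
        for p in profs:
            seqs.extend([p.labels()] * p.n)
        n = len(seqs)
        tot = sum(
            len(seqs[i] ^ seqs[j])
            for i in range(n)
            for j in range(i + 1, n)
        )
        oracle = tot / (n * (n - 1) / 2)
        assert mean_pairwise_differences(profs) == pytest.approx(oracle)


class TestEffectiveSize:
    @pytest.mark.parametrize(
        "theta, expected", [(15.342, 2730), (1.390, 247), (1.001, 178), (0, 0)]
    )
    def test_printed_values(self, theta, expected):
        assert effective_size(theta) == expected


class TestTajimasD:
    def test_zero_when_k_equals_watterson(self):
        a1 = sum(1 / i for i in range(1, 12))
        assert tajimas_d(7, 7 / a1, 12) == pytest.approx(0.0)

    def test_against_symbolic_evaluation_n4(self):
        # independent term-by-term evaluation of the variance formula
        n, S, k = 4, 3, 1.5
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajimas_d(S, k, n) == pytest.approx(expected, abs=1e-10)

    def test_matches_dendropy_on_toy_alignment(self):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import popgenstat

        seqs = {
            "s1": "AAAAAAAAAA",
            "s2": "AAAAAAAAAT",
            "s3": "AATAAAAAAT",
            "s4": "AATTAAAAAT",
        }
        mat = dendropy.DnaCharacterMatrix.from_dict(seqs)
        ks = [
            sum(a != b for a, b in zip(seqs[x], seqs[y]))
            for x, y in itertools.combinations(seqs, 2)
        ]
        ours = tajimas_d(3, float(np.mean(ks)), 4)
        assert ours == pytest.approx(popgenstat.tajimas_d(mat), abs=1e-10)


class TestFuFs:
    def test_ewens_pmf_vs_crp_enumeration(self):
        """Ewens allele-count pmf equals the exact Chinese-restaurant
        recursion (independent of the Stirling-number route)."""
        for n, theta in [(5, 1.3), (6, 0.4), (6, 3.7)]:

            @lru_cache(maxsize=None)
            def crp(i, k, theta=theta):
                if i == 0:
                    return 1.0 if k == 0 else 0.0
                p_new = theta / (theta + i - 1)
                return crp(i - 1, k - 1) * p_new + crp(i - 1, k) * (1 - p_new)

            pmf = np.exp(ewens_log_pmf(n, theta))
            for k in range(1, n + 1):
                assert pmf[k] == pytest.approx(crp(n, k), abs=1e-12)

    def test_fs_sign_behavior(self):
        # many alleles given low diversity -> strongly negative Fs
        assert fu_fs(K=6, k=0.8, n=8) < 0
        # few alleles given high diversity -> positive Fs
        assert fu_fs(K=2, k=4.0, n=8) > 0

    def test_fs_finite_at_moderate_n(self):
        assert math.isfinite(fu_fs(K=40, k=6.2, n=100))


class TestR2:
    def test_hand_computed_small_case(self):
        # n=4, S=2, k=1.0, singletons U=(1,1,0,0)
        expected = math.sqrt(((0.5) ** 2 * 2 + (0.5) ** 2 * 2) / 4) / 2
        assert r2_statistic([1, 1, 0, 0], 1.0, 2, 4) == pytest.approx(expected)

    def test_singleton_extraction(self):
        profs = _profiles([(("100T",), 1), (("200C", "300G"), 1), ((), 2)])
        # 100T, 200C, 300G each carried by exactly one sequence
        assert sorted(singletons_per_sequence(profs)) == [0, 0, 1, 2]
        assert segregating_labels(profs) == ["100T", "200C", "300G"]


class TestSummarize:
    def test_summary_consistency(self):
        profs = _profiles([(("100T",), 3), (("100T", "200C"), 2), ((), 1)])
        s = summarize(profs, L=1124)
        assert s.n == 6 and s.K == 3 and s.S == 2
        assert s.thetaS_locus == pytest.approx(s.thetaS_site * 1124)
        assert 0 <= s.Hd <= 1


class TestNeutralityPvalues:
    def test_identical_seeds_identical_pvalues(self):
        profs = _profiles([(("100T",), 3), (("200C",), 3), (("100T", "300G"), 2)])
        a = neutrality_pvalues(profs, n_sims=1000, seed=7)
        b = neutrality_pvalues(profs, n_sims=1000, seed=7)
        assert (a.p_D, a.p_Fs, a.p_R2) == (b.p_D, b.p_Fs, b.p_R2)

    def test_s_zero_flagged_undefined(self):
        profs = _profiles([((), 5)])
        res = neutrality_pvalues(profs, n_sims=1000, seed=1)
        assert not res.defined and res.p_D is None

    def test_minimum_simulations_enforced(self):
        profs = _profiles([(("100T",), 3), (("200C",), 3)])
        with pytest.raises(ValueError):
            neutrality_pvalues(profs, n_sims=10, seed=1)
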