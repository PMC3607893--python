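"""Summary statistics and neutrality tests for haplotype samples.

Implements the per-group summary block (n, haplotypes, segregating sites,
haplotype diversity, nucleotide diversity, Watterson's theta, effective
female population size) and the three expansion-sensitive neutrality
statistics: Tajima's D, Fu's Fs and Ramos-Onsins & Rozas' R2, with
Monte-Carlo p-values from a fixed-S Hudson coalescent null.

Conventions
-----------
* Pairwise differences count indels as single fifth-state events.
* A "segregating site" is a variant label carried by some but not all
  sampled sequences.
* For the neutrality tests the growth-significant direction is the low
  tail for all three statistics (D and Fs strongly negative, R2 small),
  following each statistic's source definition; the tail is an option.
* Fu's Fs uses the Ewens sampling distribution of the number of alleles
  given theta-hat = mean pairwise differences, evaluated with a log-space
  Stirling-number recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .calibration import DEFAULT_CALIBRATION, RateCalibration
from .distances import weighted_distance
from .sequences import HaplotypeProfile

__all__ = [
    "DiversitySummary",
    "NeutralityResult",
    "haplotype_diversity",
    "watterson_theta",
    "nucleotide_diversity",
    "mean_pairwise_differences",
    "effective_size",
    "tajimas_d",
    "fu_fs",
    "r2_statistic",
    "segregating_labels",
    "singletons_per_sequence",
    "summarize",
    "neutrality_pvalues",
    "simulate_fixed_s",
]


# ---------------------------------------------------------------------------
# basic estimators


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Unbiased haplotype diversity Hd = n/(n-1) (1 - sum p_i^2)."""
    counts = [int(c) for c in counts]
    if any(c <= 0 for c in counts):
        raise ValueError("haplotype counts must be positive")
    n = sum(counts)
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * (1.0 - sum_p2)


def harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def watterson_theta(S: int, n: int, L: float | None = None) -> tuple[float, float]:
    """Watterson's theta from S segregating sites in n sequences.

    Returns ``(theta_locus, theta_site)``; ``theta_site`` is ``None``-less:
    computed with effective length ``L`` (defaults to the locus length 1 if
    not given, making both values equal).
    """
    if n < 2:
        raise ValueError("watterson_theta needs n >= 2")
    if S < 0:
        raise ValueError("S must be non-negative")
    theta_locus = S / harmonic(n)
    theta_site = theta_locus / (L if L else 1.0)
    return theta_locus, theta_site


def mean_pairwise_differences(
    profiles: Sequence[HaplotypeProfile],
    weights=None,
) -> float:
    """Mean number of pairwise differences k over all unordered pairs."""
    n = sum(p.n for p in profiles)
    if n < 2:
        raise ValueError("needs n >= 2 sequences")
    total = 0.0
    for i, a in enumerate(profiles):
        for j in range(i + 1, len(profiles)):
            b = profiles[j]
            total += a.n * b.n * weighted_distance(a, b, weights)
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(
    profiles: Sequence[HaplotypeProfile],
    L: float,
    weights=None,
) -> float:
    """Nucleotide diversity pi: mean pairwise differences per site."""
    if L <= 0:
        raise ValueError("effective length must be positive")
    return mean_pairwise_differences(profiles, weights) / L


def effective_size(
    theta_locus: float,
    cal: RateCalibration = DEFAULT_CALIBRATION,
) -> int:
    """Effective female population size Ne = theta / (2 u) with u the
    per-locus per-generation mutation rate, rounded to an integer."""
    if theta_locus < 0:
        raise ValueError("theta must be non-negative")
    return int(round(theta_locus / (2.0 * cal.u_locus_gen)))


def segregating_labels(profiles: Sequence[HaplotypeProfile]) -> list[str]:
    """Variant labels present in some but not all sampled sequences."""
    n = sum(p.n for p in profiles)
    carriers: dict[str, int] = {}
    for p in profiles:
        for lab in p.labels():
            carriers[lab] = carriers.get(lab, 0) + p.n
    return sorted(lab for lab, c in carriers.items() if 0 < c < n)


def singletons_per_sequence(profiles: Sequence[HaplotypeProfile]) -> list[int]:
    """Folded singleton count U_i for each of the n sequences.

    A site is a singleton when its minority state is carried by exactly one
    sequence; that sequence's U increases by one.  Sequences are expanded
    according to haplotype multiplicities.
    """
    n = sum(p.n for p in profiles)
    carriers: dict[str, int] = {}
    for p in profiles:
        for lab in p.labels():
            carriers[lab] = carriers.get(lab, 0) + p.n
    U = []
    for p in profiles:
        u = 0
        for lab, c in carriers.items():
            has = lab in p.labels()
            if c == 1 and has and p.n == 1:
                u += 1
            elif c == n - 1 and not has and p.n == 1:
                u += 1
        U.extend([u] * p.n)
    return U


# ---------------------------------------------------------------------------
# neutrality statistics


def tajimas_d(S: int, k: float, n: int) -> float:
    """Tajima's D from S segregating sites and mean pairwise differences k."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S == 0:
        raise ValueError("Tajima's D undefined for S = 0")
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (k - S / a1) / math.sqrt(var)


@lru_cache(maxsize=32)
def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = np.full(n + 1, -np.inf)
    row[:2] = [-np.inf, 0.0]  # s(1,1)=1
    if n == 1:
        return row
    for m in range(2, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1 : m + 1] = np.logaddexp(
            row[0:m], math.log(m - 1) + row[1 : m + 1]
        )
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) under the Ewens sampling formula, k=0..n."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = _log_stirling_row(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    k = np.arange(n + 1)
    return logs + k * math.log(theta) - log_rising


def fu_fs(K: int, k: float, n: int) -> float:
    """Fu's Fs = ln(S'/(1-S')) with S' = P(#alleles >= K | theta = k)."""
    if n < 2 or K < 1 or K > n:
        raise ValueError("invalid K or n for Fu's Fs")
    if k <= 0:
        raise ValueError("Fu's Fs undefined when mean pairwise differences = 0")
    logp = ewens_log_pmf(n, k)
    with np.errstate(over="ignore"):
        p = np.exp(logp - logp.max())
    p /= p.sum()
    s_prime = float(p[K:].sum())
    eps = 1e-15
    s_prime = min(max(s_prime, eps), 1 - eps)
    return math.log(s_prime / (1.0 - s_prime))


def r2_statistic(U: Sequence[int], k: float, S: int, n: int) -> float:
    """Ramos-Onsins & Rozas R2 from per-sequence singleton counts."""
    if S <= 0:
        raise ValueError("R2 undefined for S = 0")
    if len(U) != n:
        raise ValueError("need one singleton count per sequence")
    ss = sum((u - k / 2.0) ** 2 for u in U) / n
    return math.sqrt(ss) / S


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    K: int
    S: int
    Hd: float
    pi: float
    thetaS_site: float
    thetaS_locus: float
    Ne: int


@dataclass(frozen=True)
class NeutralityResult:
    D: float | None
    Fs: float | None
    R2: float | None
    p_D: float | None
    p_Fs: float | None
    p_R2: float | None
    n_sims: int
    seed: int
    defined: bool = True


def summarize(
    profiles: Sequence[HaplotypeProfile],
    L: float | None = None,
    cal: RateCalibration = DEFAULT_CALIBRATION,
) -> DiversitySummary:
    """Table-style diversity summary for one group of haplotype profiles.

    ``L`` is the effective number of sites for per-site statistics and
    defaults to the calibration's locus length.
    """
    L = float(L if L is not None else cal.L)
    n = sum(p.n for p in profiles)
    if n < 2:
        raise ValueError("summary needs n >= 2 sequences")
    S = len(segregating_labels(profiles))
    theta_locus, theta_site = watterson_theta(S, n, L)
    return DiversitySummary(
        n=n,
        K=len(profiles),
        S=S,
        Hd=haplotype_diversity([p.n for p in profiles]),
        pi=nucleotide_diversity(profiles, L),
        thetaS_site=theta_site,
        thetaS_locus=theta_locus,
        Ne=effective_size(theta_locus, cal),
    )


# ---------------------------------------------------------------------------
# fixed-S coalescent null and Monte-Carlo p-values


def simulate_fixed_s(
    n: int, S: int, rng: np.random.Generator
) -> tuple[float, int, list[int]]:
    """One Hudson coalescent sample of n sequences conditioned on S sites.

    Builds a neutral constant-size coalescent genealogy, drops the S
    mutations on branches proportionally to branch length, and returns
    ``(mean pairwise differences, #haplotypes, singletons per sequence)``.
    """
    if n < 2:
        raise ValueError("n >= 2 required")
    masks: list[int] = [1 << i for i in range(n)]
    birth = [0.0] * n
    t = 0.0
    branches: list[int] = []
    lengths: list[float] = []
    while len(masks) > 1:
        kk = len(masks)
        t += rng.exponential(2.0 / (kk * (kk - 1)))
        i, j = rng.choice(kk, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        for idx in (i, j):
            branches.append(masks[idx])
            lengths.append(t - birth[idx])
        merged = masks[i] | masks[j]
        masks = [m for r, m in enumerate(masks) if r not in (i, j)] + [merged]
        birth = [b for r, b in enumerate(birth) if r not in (i, j)] + [t]
    lengths_arr = np.asarray(lengths)
    probs = lengths_arr / lengths_arr.sum()
    hit = rng.choice(len(branches), size=S, p=probs)
    site_masks = [branches[h] for h in hit]

    npairs = n * (n - 1) / 2.0
    k_mean = sum(
        (c := m.bit_count()) * (n - c) for m in site_masks
    ) / npairs
    sigs: dict[int, list[int]] = {i: [] for i in range(n)}
    U = [0] * n
    for s_idx, m in enumerate(site_masks):
        c = m.bit_count()
        mm = m
        while mm:
            low = mm & -mm
            sigs[low.bit_length() - 1].append(s_idx)
            mm ^= low
        if c == 1:
            U[m.bit_length() - 1] += 1
        elif c == n - 1:
            U[((1 << n) - 1 ^ m).bit_length() - 1] += 1
    K = len({tuple(v) for v in sigs.values()})
    return k_mean, K, U


def _stats_from_sim(
    n: int, S: int, k_mean: float, K: int, U: list[int]
) -> tuple[float, float, float]:
    D = tajimas_d(S, k_mean, n)
    Fs = fu_fs(K, k_mean, n) if k_mean > 0 else math.inf
    R2 = r2_statistic(U, k_mean, S, n)
    return D, Fs, R2


def null_distribution(
    n: int,
    S: int,
    n_sims: int,
    seed: int,
) -> np.ndarray:
    """Joint null distribution of (D, Fs, R2) under fixed-S neutrality.

    Returns an ``(n_sims, 3)`` array.  Cache the result when computing
    p-values for many samples that share (n, S).
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_sims, 3))
    for r in range(n_sims):
        k_mean, K, U = simulate_fixed_s(n, S, rng)
        if k_mean == 0:
            out[r] = (0.0, math.inf, math.inf)
            continue
        out[r] = _stats_from_sim(n, S, k_mean, K, U)
    return out


def neutrality_pvalues(
    profiles: Sequence[HaplotypeProfile],
    n_sims: int = 1000,
    seed: int = 0,
    tail: str = "low",
    null: np.ndarray | None = None,
) -> NeutralityResult:
    """Observed D/Fs/R2 with Monte-Carlo p-values.

    The null conditions on the observed number of segregating sites S
    (fixed-S Hudson simulations).  ``tail='low'`` treats small values of
    all three statistics as the growth direction; p-values are
    ``(#{as-or-more-extreme} + 1)/(n_sims + 1)``.  Pass a precomputed
    ``null`` array (from :func:`null_distribution`) to share simulations
    across groups with equal (n, S).
    """
    if n_sims < 1000 and null is None:
        raise ValueError("n_sims must be at least 1000")
    if tail not in ("low", "high"):
        raise ValueError("tail must be 'low' or 'high'")
    n = sum(p.n for p in profiles)
    S = len(segregating_labels(profiles))
    if S == 0 or n < 4:
        return NeutralityResult(
            None, None, None, None, None, None, n_sims, seed, defined=False
        )
    k = mean_pairwise_differences(profiles)
    D = tajimas_d(S, k, n)
    Fs = fu_fs(len(profiles), k, n) if k > 0 else math.inf
    R2 = r2_statistic(singletons_per_sequence(profiles), k, S, n)

    if null is None:
        null = null_distribution(n, S, n_sims, seed)
    m = null.shape[0]

    def pval(obs: float, col: int) -> float:
        sims = null[:, col]
        if tail == "low":
            hits = int(np.sum(sims <= obs))
        else:
            hits = int(np.sum(sims >= obs))
        return (hits + 1) / (m + 1)

    return NeutralityResult(
        D=D,
        Fs=Fs,
        R2=R2,
        p_D=pval(D, 0),
        p_Fs=pval(Fs, 1),
        p_R2=pval(R2, 2),
        n_sims=m,
        seed=seed,
    )
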