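"""Mismatch distributions and sudden-expansion model fitting.

The observed mismatch distribution is the histogram of pairwise sequence
differences over all unordered pairs.  The sudden-expansion model assumes
a population at mutation-scaled size theta0 that grew instantaneously to
theta1 at tau/2 mutation-time units ago (tau = 2ut with u the per-locus
per-generation rate and t the age in generations).  The expected pairwise
difference distribution is

    F_j(tau, theta0, theta1)
        = Fhat_j(theta1) * P[Gamma(j+1, (theta1+1)/theta1) <= tau]
        + exp(-tau (theta1+1)/theta1)
          * sum_{i=0}^{j} tau^i/i! * Fhat_{j-i}(theta0)

with the geometric equilibrium Fhat_j(theta) = theta^j / (1+theta)^{j+1}:
the first term covers pairs coalescing after the expansion, the second
pairs predating it (Poisson(tau) recent mutations on top of the old
equilibrium).  Parameters are fitted by least squares (Nelder-Mead from a
method-of-moments start), the fit is tested by parametric bootstrap of the
sum of squared deviations (SSD), and shape is summarized by Harpending's
raggedness index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .calibration import DEFAULT_CALIBRATION, RateCalibration
from .distances import weighted_distance
from .sequences import HaplotypeProfile

THETA1_CAP = 1.0e5


@dataclass(frozen=True)
class MismatchDistribution:
    """Pairwise-difference histogram: counts[i] unordered pairs differ by i."""

    counts: tuple[float, ...]
    n: int  # number of sequences

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("mismatch distribution needs n >= 2 sequences")
        expected_pairs = self.n * (self.n - 1) / 2
        if not math.isclose(sum(self.counts), expected_pairs, rel_tol=1e-9):
            raise ValueError("pair counts do not sum to n(n-1)/2")

    @property
    def n_pairs(self) -> float:
        return sum(self.counts)

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1

    def relative(self) -> np.ndarray:
        return np.asarray(self.counts) / self.n_pairs

    def mean(self) -> float:
        rel = self.relative()
        return float(np.dot(np.arange(len(rel)), rel))


def mismatch_distribution(
    profiles: Sequence[HaplotypeProfile],
    weights=None,
) -> MismatchDistribution:
    """Observed mismatch distribution, weighted by haplotype multiplicity."""
    n = sum(p.n for p in profiles)
    if n < 2:
        raise ValueError("needs n >= 2 sequences")
    counts: dict[int, float] = {}
    for i, a in enumerate(profiles):
        if a.n > 1:  # identical pairs within a haplotype
            counts[0] = counts.get(0, 0) + a.n * (a.n - 1) / 2
        for j in range(i + 1, len(profiles)):
            b = profiles[j]
            d = int(round(weighted_distance(a, b, weights)))
            counts[d] = counts.get(d, 0) + a.n * b.n
    d_max = max(counts) if counts else 0
    return MismatchDistribution(
        tuple(counts.get(i, 0.0) for i in range(d_max + 1)), n=n
    )


# ---------------------------------------------------------------------------
# model


def _equilibrium(theta: float, j: np.ndarray) -> np.ndarray:
    if theta <= 0:
        return np.where(j == 0, 1.0, 0.0)
    return np.exp(j * math.log(theta) - (j + 1) * math.log1p(theta))


def expected_mismatch(
    tau: float,
    theta0: float,
    theta1: float,
    i: int | np.ndarray,
) -> float | np.ndarray:
    """Model probability that a pair differs by i sites (vectorized in i)."""
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise ValueError("model parameters must be non-negative")
    scalar = np.isscalar(i)
    j = np.atleast_1d(np.asarray(i, dtype=int))
    if np.any(j < 0):
        raise ValueError("difference class must be non-negative")
    th1 = max(theta1, 1e-12)
    rate = (th1 + 1.0) / th1
    jmax = int(j.max())
    idx = np.arange(jmax + 1)
    eq1 = _equilibrium(theta1, idx)
    eq0 = _equilibrium(theta0, idx)
    # pairs coalescing since the expansion
    recent = eq1[j] * special.gammainc(j + 1, rate * tau)
    # pairs predating it: Poisson(tau) recent mutations on the old equilibrium
    log_pois = -tau + idx * math.log(tau) - special.gammaln(idx + 1) if tau > 0 else None
    if tau > 0:
        pois = np.exp(log_pois)
    else:
        pois = np.where(idx == 0, 1.0, 0.0)
    conv = np.convolve(pois, eq0)[: jmax + 1]
    old = math.exp(-rate * tau + tau) * conv[j] if rate * tau - tau < 700 else 0.0
    out = recent + old
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    SSD: float
    raggedness: float
    p_SSD: float | None = None
    p_raggedness: float | None = None
    tau_ci: tuple[float, float] | None = None
    converged: bool = True
    n_boot: int = 0
    seed: int = 0


def raggedness(rel_freqs: Sequence[float]) -> float:
    """Harpending's raggedness: sum of squared successive differences of the
    relative mismatch frequencies (with a trailing zero class appended)."""
    x = list(rel_freqs) + [0.0]
    return float(sum((x[i] - x[i - 1]) ** 2 for i in range(1, len(x))))


def _ssd(params: np.ndarray, obs_rel: np.ndarray) -> float:
    tau, th0, th1 = np.exp(np.clip(params, -30.0, 30.0))
    th1 = min(th1, THETA1_CAP)
    exp_rel = expected_mismatch(tau, th0, th1, np.arange(len(obs_rel)))
    return float(np.sum((obs_rel - exp_rel) ** 2))


def fit_expansion(
    obs: MismatchDistribution,
    n_boot: int = 1000,
    seed: int = 0,
    bootstrap: bool = True,
) -> ExpansionFit:
    """Least-squares sudden-expansion fit with parametric-bootstrap SSD test.

    The optimizer is a derivative-free simplex started from the method of
    moments (tau = observed mean pairwise differences, small theta0, large
    theta1); theta1 is capped at 1e5 to emulate the infinite-growth
    convention.  ``p_SSD``/``p_raggedness`` are the fractions of bootstrap
    replicates simulated under the fitted model whose refitted SSD (or
    raggedness) is as large or larger than observed.
    """
    obs_rel = obs.relative()
    k = obs.mean()
    if obs.d_max == 0:
        return ExpansionFit(0.0, 0.0, 0.0, 0.0, raggedness(obs_rel),
                            converged=True, n_boot=0, seed=seed)
    start = np.log([max(k, 0.1), max(0.1, k / 10), 1000.0])
    res = optimize.minimize(
        _ssd, start, args=(obs_rel,), method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-12},
    )
    tau, th0, th1 = np.exp(np.clip(res.x, -30.0, 30.0))
    th1 = min(th1, THETA1_CAP)
    fit = ExpansionFit(
        tau=float(tau),
        theta0=float(th0),
        theta1=float(th1),
        SSD=float(res.fun),
        raggedness=raggedness(obs_rel),
        converged=bool(res.success),
        n_boot=0,
        seed=seed,
    )
    if not bootstrap or n_boot <= 0:
        return fit

    rng = np.random.default_rng(seed)
    hits_ssd = 0
    hits_rag = 0
    taus = []
    for _ in range(n_boot):
        sim = simulate_mismatch(obs.n, fit.tau, fit.theta0, fit.theta1, rng)
        refit = fit_expansion(sim, bootstrap=False)
        taus.append(refit.tau)
        if refit.SSD >= fit.SSD:
            hits_ssd += 1
        if refit.raggedness >= fit.raggedness:
            hits_rag += 1
    lo, hi = np.percentile(taus, [2.5, 97.5])
    return ExpansionFit(
        tau=fit.tau,
        theta0=fit.theta0,
        theta1=fit.theta1,
        SSD=fit.SSD,
        raggedness=fit.raggedness,
        p_SSD=(hits_ssd + 1) / (n_boot + 1),
        p_raggedness=(hits_rag + 1) / (n_boot + 1),
        tau_ci=(float(lo), float(hi)),
        converged=fit.converged,
        n_boot=n_boot,
        seed=seed,
    )


def simulate_mismatch(
    n: int,
    tau: float,
    theta0: float,
    theta1: float,
    rng: np.random.Generator,
) -> MismatchDistribution:
    """Simulate one sample's mismatch distribution under the step model.

    The coalescent runs in mutation-time units (per-branch mutation rate 1,
    k-lineage coalescence rate k(k-1)/theta with theta = theta1 more
    recently than tau/2 and theta0 before); mutations follow an
    infinite-sites Poisson process on the branches.
    """
    masks = [1 << i for i in range(n)]
    birth = [0.0] * n
    t = 0.0
    branches: list[tuple[int, float]] = []
    t_switch = tau / 2.0
    while len(masks) > 1:
        kk = len(masks)
        theta = theta1 if t < t_switch else theta0
        rate = kk * (kk - 1) / max(theta, 1e-12)
        wait = rng.exponential(1.0 / rate)
        if t < t_switch and t + wait > t_switch:
            # re-draw in the pre-expansion epoch (memorylessness)
            t = t_switch
            continue
        t += wait
        i, j = sorted(int(x) for x in rng.choice(kk, size=2, replace=False))
        for idx in (i, j):
            branches.append((masks[idx], t - birth[idx]))
        merged = masks[i] | masks[j]
        masks = [m for r, m in enumerate(masks) if r not in (i, j)] + [merged]
        birth = [b for r, b in enumerate(birth) if r not in (i, j)] + [t]
    muts = []
    for mask, length in branches:
        for _ in range(rng.poisson(length)):
            muts.append(mask)
    counts: dict[int, float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            d = sum(
                1 for m in muts if ((m >> a) & 1) != ((m >> b) & 1)
            )
            counts[d] = counts.get(d, 0) + 1
    d_max = max(counts) if counts else 0
    return MismatchDistribution(
        tuple(counts.get(i, 0.0) for i in range(d_max + 1)), n=n
    )


def tau_to_years(
    tau: float, cal: RateCalibration = DEFAULT_CALIBRATION
) -> float:
    """Convert tau = 2ut to years: years = tau * years_per_mutation / 2."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return tau * cal.years_per_mutation / 2.0
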