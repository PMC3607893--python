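"""Population structure: PhiST, UPGMA, geography and Mantel tests.

Between-population differentiation is measured by PhiST, the AMOVA
variance decomposition of pairwise inter-haplotype distances (the
fifth-state weighted variant-count distance by default); setting every
distance to 0/1 identity gives the classical haplotype-frequency Fst.
Population trees use UPGMA (average linkage) on the distance matrix,
geographic distances are great-circle kilometres, and
isolation-by-distance is assessed by distance-distance regression and the
Mantel permutation test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .distances import weighted_distance

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class PopulationSample:
    """One population: code, optional coordinates, haplotype counts."""

    code: str
    haplotypes: Mapping[Hashable, int] = field(default_factory=dict)
    name: str = ""
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.haplotypes.values()):
            raise ValueError("haplotype counts must be positive")
        object.__setattr__(self, "haplotypes", dict(self.haplotypes))

    @property
    def n(self) -> int:
        return sum(self.haplotypes.values())


# ---------------------------------------------------------------------------
# PhiST / Fst


def _pair_ss(
    counts: Sequence[tuple[Hashable, int]],
    dist2: Callable[[Hashable, Hashable], float],
) -> float:
    """Sum over unordered sequence pairs of squared inter-haplotype distance."""
    total = 0.0
    for i, (h, c) in enumerate(counts):
        for j in range(i + 1, len(counts)):
            g, d = counts[j]
            total += c * d * dist2(h, g)
    return total


def phi_st_pair(
    a: PopulationSample,
    b: PopulationSample,
    dist2: Callable[[Hashable, Hashable], float],
) -> float:
    """PhiST between two populations by AMOVA variance decomposition.

    ``dist2`` returns the squared molecular distance between two haplotype
    objects.  Negative estimates (sampling noise around zero) are returned
    as computed.
    """
    na, nb = a.n, b.n
    N = na + nb
    if na < 2 or nb < 2:
        raise ValueError("each population needs n >= 2")
    items_a = sorted(a.haplotypes.items(), key=lambda kv: str(kv[0]))
    items_b = sorted(b.haplotypes.items(), key=lambda kv: str(kv[0]))
    ss_a = _pair_ss(items_a, dist2)
    ss_b = _pair_ss(items_b, dist2)
    ss_total = ss_a + ss_b
    for h, c in items_a:
        for g, d in items_b:
            ss_total += c * d * dist2(h, g)
    ss_total /= N
    ss_within = ss_a / na + ss_b / nb
    ss_among = ss_total - ss_within
    df_within = N - 2
    ms_within = ss_within / df_within
    ms_among = ss_among / 1.0
    n_prime = (N - (na * na + nb * nb) / N) / 1.0
    sigma2_a = (ms_among - ms_within) / n_prime
    sigma2_w = ms_within
    denom = sigma2_a + sigma2_w
    if denom == 0:
        return 0.0
    return sigma2_a / denom


def pairwise_fst(
    populations: Sequence[PopulationSample],
    mode: str = "phi_st",
    weights: Mapping[int, float] | None = None,
    min_n: int = 10,
    include_small: bool = False,
) -> pd.DataFrame:
    """Pairwise PhiST (or haplotype-frequency Fst) matrix.

    ``mode='phi_st'`` uses the weighted variant-count distance between
    haplotypes; ``mode='frequency'`` scores haplotypes 0/1 identical or
    not.  Populations with fewer than ``min_n`` sequences are excluded
    unless ``include_small``.
    """
    if mode not in ("phi_st", "frequency"):
        raise ValueError("mode must be 'phi_st' or 'frequency'")
    kept = [p for p in populations if include_small or p.n >= min_n]
    if len(kept) < 2:
        raise ValueError("need at least two populations after the n filter")
    codes = [p.code for p in kept]
    if len(set(codes)) != len(codes):
        raise ValueError("population codes must be unique")

    if mode == "phi_st":
        def dist2(h, g):
            return weighted_distance(h, g, weights)
    else:
        def dist2(h, g):
            return 0.0 if h == g else 1.0

    mat = pd.DataFrame(0.0, index=codes, columns=codes)
    for i, a in enumerate(kept):
        for j in range(i + 1, len(kept)):
            v = phi_st_pair(a, kept[j], dist2)
            mat.iloc[i, j] = mat.iloc[j, i] = v
    return mat


# ---------------------------------------------------------------------------
# UPGMA


def upgma(matrix: pd.DataFrame) -> TreeNode:
    """UPGMA (average-linkage) tree from a symmetric distance matrix.

    Negative entries are clamped to zero (with a warning); the returned
    scikit-bio tree is ultrametric with tip-to-root height half the
    cophenetic distance.  Serialize with ``str(tree)`` (newick).
    """
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    labels = list(matrix.index)
    d = matrix.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        warnings.warn("negative distances clamped to 0 for UPGMA")
        d = np.clip(d, 0.0, None)
    np.fill_diagonal(d, 0.0)
    linkage = average(squareform(d, checks=False))
    # tips sit at depth (cophenetic distance)/2: the usual UPGMA convention
    return TreeNode.from_linkage_matrix(linkage, labels)


# ---------------------------------------------------------------------------
# geography


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    for lat, lon in (a, b):
        if not (-90 <= lat <= 90 and -180 <= lon <= 360):
            raise ValueError(f"coordinates out of range: {(lat, lon)}")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    s = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def geographic_matrix(populations: Sequence[PopulationSample]) -> pd.DataFrame:
    codes = [p.code for p in populations]
    mat = pd.DataFrame(0.0, index=codes, columns=codes)
    for i, a in enumerate(populations):
        if a.lat is None or a.lon is None:
            raise ValueError(f"population {a.code} lacks coordinates")
        for j in range(i + 1, len(populations)):
            b = populations[j]
            km = great_circle_km((a.lat, a.lon), (b.lat, b.lon))
            mat.iloc[i, j] = mat.iloc[j, i] = km
    return mat


# ---------------------------------------------------------------------------
# Mantel and regression


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None = None
    method: str = "permutation"


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel(
    genetic: pd.DataFrame,
    geographic: pd.DataFrame,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "permutation",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper off-diagonal triangles; the
    one-sided p-value permutes rows+columns of one matrix jointly,
    ``p = (#{r_perm >= r_obs} + 1)/(N + 1)``.  ``method='exact'``
    enumerates all n! permutations (identity included) and reports the
    exact fraction with r_perm >= r_obs.
    """
    if list(genetic.index) != list(geographic.index):
        raise ValueError("matrices must share the same population order")
    n = genetic.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 populations")
    x = genetic.to_numpy(dtype=float)
    y = geographic.to_numpy(dtype=float)
    xv = _upper(x)
    if np.std(xv) == 0 or np.std(_upper(y)) == 0:
        raise ValueError("zero-variance distance matrix")
    r_obs = float(stats.pearsonr(xv, _upper(y))[0])

    if method == "exact":
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            yp = y[np.ix_(perm, perm)]
            total += 1
            if stats.pearsonr(xv, _upper(yp))[0] >= r_obs - 1e-12:
                hits += 1
        return MantelResult(r_obs, hits / total, total, method="exact")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = y[np.ix_(perm, perm)]
        if stats.pearsonr(xv, _upper(yp))[0] >= r_obs:
            hits += 1
    return MantelResult(
        r_obs, (hits + 1) / (n_permutations + 1), n_permutations, seed=seed
    )


def distance_regression(
    genetic: pd.DataFrame, geographic: pd.DataFrame
) -> tuple[float, float, float]:
    """OLS of genetic on geographic distance over the upper triangles.

    Returns (slope, intercept, p_slope)."""
    if list(genetic.index) != list(geographic.index):
        raise ValueError("matrices must share the same population order")
    res = stats.linregress(
        _upper(geographic.to_numpy(float)), _upper(genetic.to_numpy(float))
    )
    return float(res.slope), float(res.intercept), float(res.pvalue)


# ---------------------------------------------------------------------------
# frequency surfaces


def frequency_surface(
    populations: Sequence[PopulationSample],
    frequencies: Mapping[str, float],
    grid: tuple[float, float, float, float] = (-35.0, -15.0, 10.0, 35.0),
    n_cells: int = 50,
    power: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-distance-weighted haplogroup-frequency surface.

    ``grid`` is (lat_min, lat_max, lon_min, lon_max).  Returns (lats,
    lons, surface) with surface[i, j] the interpolated frequency at
    (lats[i], lons[j]), clipped to [0, 1] and exact at sample coordinates.
    """
    pts = [
        (p.lat, p.lon, frequencies[p.code])
        for p in populations
        if p.code in frequencies
    ]
    if len(pts) < 2:
        raise ValueError("need at least two populations with frequencies")
    for lat, lon, f in pts:
        if lat is None or lon is None:
            raise ValueError("all interpolated populations need coordinates")
    lat_min, lat_max, lon_min, lon_max = grid
    lats = np.linspace(lat_min, lat_max, n_cells)
    lons = np.linspace(lon_min, lon_max, n_cells)
    if not any(
        lat_min <= lat <= lat_max and lon_min <= lon <= lon_max
        for lat, lon, _ in pts
    ):
        warnings.warn("grid does not cover any sample point")
    surface = np.zeros((n_cells, n_cells))
    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            num = den = 0.0
            exact = None
            for lat, lon, f in pts:
                d = great_circle_km((la, lo), (lat, lon))
                if d < 1e-9:
                    exact = f
                    break
                w = 1.0 / d**power
                num += w * f
                den += w
            surface[i, j] = exact if exact is not None else num / den
    return lats, lons, np.clip(surface, 0.0, 1.0)
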