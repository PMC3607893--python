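"""Coalescent synthetic data with the structure the analyses assume.

Generates single-locus samples of two-segment control-region haplotypes:

* a Hudson coalescent genealogy under a constant-size, sudden-expansion
  or exponential-growth demography, in mutation-time units (per-branch
  mutation rate 1, so branch lengths are expected mutation counts and a
  clade's depth is its TMRCA in mutations);
* finite-sites mutations placed by a Poisson process on branches, with a
  transition:transversion bias (default 5.6:1) and a small indel channel
  (default 2% of events) outside the excluded 303-315 tract — so
  reversions and fifth-state events arise naturally;
* sequences emitted relative to the reference, ready for the alignment /
  variant-calling pipeline, together with the full ground truth
  (genealogy, TMRCA, demographic parameters, per-tip clade labels).

``seed_motifs`` instead plants haplogroup motif paths from a
:class:`~mitopop.haplogroups.MotifTree` at chosen per-population
frequencies, for classifier and structure round-trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .calibration import DEFAULT_CALIBRATION
from .haplogroups import MotifTree
from .reference import EXCLUDED_TRACT, ReferenceSegments, default_reference
from .rho import RootedGenealogy
from .sequences import apply_variants
from .variants import Variant, parse_variant_label

import networkx as nx


@dataclass(frozen=True)
class DemographicModel:
    """constant(theta) | sudden_expansion(tau, theta0, theta1) |
    exponential(theta, rate) — all in mutational units."""

    kind: str = "constant"
    theta: float = 5.0
    tau: float = 0.0
    theta0: float = 0.0
    theta1: float = 0.0
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sudden_expansion", "exponential"):
            raise ValueError(f"unknown demographic model {self.kind!r}")
        for v in (self.theta, self.tau, self.theta0, self.theta1):
            if v < 0:
                raise ValueError("demographic parameters must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    n: int = 60
    kappa: float = 5.6
    indel_rate: float = 0.02
    seed: int = 0
    reference: ReferenceSegments = field(default_factory=default_reference)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n >= 2 required")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0 <= self.indel_rate < 1):
            raise ValueError("indel_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimulatedTruth:
    genealogy: RootedGenealogy
    tmrca_mutations: float
    model: DemographicModel
    tip_variants: Mapping[str, tuple[Variant, ...]]
    clade_labels: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0
    event_counts: Mapping[str, int] = field(default_factory=dict)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def _coalescent_genealogy(
    model: DemographicModel, n: int, rng: np.random.Generator
) -> tuple[list[tuple[int, int, float]], dict[int, tuple[int, int]], float, int]:
    """Hudson genealogy in mutation-time units.

    Returns (branches as (node, parent, length), merge children map,
    tmrca, root node id).  Node ids: 0..n-1 tips, then internal.
    """
    active = list(range(n))
    birth = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    branches: list[tuple[int, int, float]] = []
    next_id = n
    t = 0.0
    while len(active) > 1:
        k = len(active)
        if model.kind == "constant":
            rate = k * (k - 1) / model.theta
            t += rng.exponential(1.0 / rate)
        elif model.kind == "sudden_expansion":
            t_switch = model.tau / 2.0
            theta = model.theta1 if t < t_switch else model.theta0
            rate = k * (k - 1) / max(theta, 1e-12)
            wait = rng.exponential(1.0 / rate)
            if t < t_switch and t + wait > t_switch:
                t = t_switch  # memoryless re-draw in the older epoch
                continue
            t += wait
        else:  # exponential growth at rate g (backwards: theta(t)=theta e^-gt)
            g = model.growth_rate
            base = k * (k - 1) / model.theta
            e = rng.exponential(1.0)
            if g == 0:
                t += e / base
            else:
                # integrated hazard: base/g (e^{g t2} - e^{g t1}) = e
                t = math.log(math.exp(g * t) + g * e / base) / g
        i, j = sorted(int(x) for x in rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        parent = next_id
        next_id += 1
        for child in (a, b):
            branches.append((child, parent, t - birth[child]))
        children[parent] = (a, b)
        active = [x for r, x in enumerate(active) if r not in (i, j)] + [parent]
        birth[parent] = t
    return branches, children, t, active[0]


def _mutate_branch(
    state: dict[int, str],
    indels: set[str],
    n_mut: int,
    positions: np.ndarray,
    ref: ReferenceSegments,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    events: dict[str, int],
) -> None:
    """Apply n_mut mutation events in place, tallying event types."""
    for _ in range(n_mut):
        pos = int(positions[rng.integers(len(positions))])
        if rng.random() < cfg.indel_rate:
            refbase = ref.base_at(pos)
            lab = (
                f"{pos}ins{refbase}" if rng.random() < 0.5 else f"{pos}del{refbase}"
            )
            indels.symmetric_difference_update({lab})  # second hit reverts
            events["indel"] = events.get("indel", 0) + 1
            continue
        cur = state.get(pos, ref.base_at(pos))
        if rng.random() < cfg.kappa / (cfg.kappa + 1.0):
            new = _TRANSITION[cur]
            events["transition"] = events.get("transition", 0) + 1
        else:
            new = _TRANSVERSIONS[cur][rng.integers(2)]
            events["transversion"] = events.get("transversion", 0) + 1
        if new == ref.base_at(pos):
            state.pop(pos, None)  # reversion to the reference state
        else:
            state[pos] = new


def simulate_coalescent(
    model: DemographicModel,
    cfg: SimulationConfig,
) -> tuple[dict[str, dict[str, str]], SimulatedTruth]:
    """Simulate sequences and ground truth under the demographic model.

    Returns ``(sequences, truth)`` where ``sequences`` maps sample id to
    ``{segment: sequence}`` emitted from the reference.
    """
    rng = np.random.default_rng(cfg.seed)
    ref = cfg.reference
    lo, hi = EXCLUDED_TRACT
    positions = np.asarray(
        [p for p in ref.positions() if not lo <= p <= hi], dtype=int
    )
    branches, children, tmrca, root = _coalescent_genealogy(model, cfg.n, rng)

    parent_of = {node: (parent, length) for node, parent, length in branches}
    mut_counts = {
        node: int(rng.poisson(length)) for node, _, length in branches
    }

    # walk root -> tips applying finite-sites mutations along each path
    tip_state: dict[int, tuple[dict[int, str], set[str]]] = {}
    genealogy = nx.DiGraph()
    genealogy.add_node(root, count=0)
    events: dict[str, int] = {}

    def descend(node: int, state: dict[int, str], indels: set[str]) -> None:
        for child in children.get(node, ()):  # () at tips
            cs, ci = dict(state), set(indels)
            _mutate_branch(
                cs, ci, mut_counts[child], positions, ref, cfg, rng, events
            )
            genealogy.add_edge(node, child, mutations=mut_counts[child])
            genealogy.nodes[child]["count"] = 1 if child < cfg.n else 0
            descend(child, cs, ci)
        if node < cfg.n:
            tip_state[node] = (state, indels)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * cfg.n + 100))
    try:
        descend(root, {}, set())
    finally:
        sys.setrecursionlimit(old_limit)

    sequences: dict[str, dict[str, str]] = {}
    tip_variants: dict[str, tuple[Variant, ...]] = {}
    for tip in range(cfg.n):
        state, indels = tip_state[tip]
        vs = [Variant(p, "substitution", b) for p, b in state.items()]
        vs += [parse_variant_label(lab) for lab in indels]
        vs = tuple(sorted(vs))
        sid = f"S{tip:04d}"
        tip_variants[sid] = vs
        sequences[sid] = apply_variants(vs, ref)

    truth = SimulatedTruth(
        genealogy=RootedGenealogy(genealogy, root),
        tmrca_mutations=tmrca,
        model=model,
        tip_variants=tip_variants,
        seed=cfg.seed,
        event_counts=events,
    )
    return sequences, truth


# ---------------------------------------------------------------------------
# motif seeding


def seed_motifs(
    tree: MotifTree,
    clade_frequencies: Mapping[str, Mapping[str, float]],
    n_per_population: Mapping[str, int],
    private_rate: float = 0.0,
    seed: int = 0,
    reference: ReferenceSegments | None = None,
) -> list[tuple[str, str, str, tuple[Variant, ...]]]:
    """Plant clade motif paths at chosen per-population frequencies.

    ``clade_frequencies`` maps population -> {clade: frequency} (each
    summing to 1); counts are apportioned by largest remainder so planted
    frequencies are exact.  Each sample carries its clade's folded motif
    path plus Poisson(private_rate) private substitutions at positions no
    motif uses.  Returns ``(sample_id, population, true_clade, variants)``
    records.
    """
    rng = np.random.default_rng(seed)
    ref = reference or default_reference()
    requested = sorted({c for f in clade_frequencies.values() for c in f})
    folded: dict[str, frozenset[str]] = {}
    pos_of: dict[int, str] = {}
    for clade in requested:
        if clade not in tree:
            raise ValueError(f"unknown clade {clade!r}")
        expected, _ = tree.expected_variants(clade)
        folded[clade] = expected
        for lab in expected:
            v = parse_variant_label(lab)
            prior = pos_of.get(v.position)
            if prior is not None and prior != lab:
                raise ValueError(
                    f"motif conflict at position {v.position}: {prior} vs {lab}"
                )
            pos_of[v.position] = lab
    motif_positions = set(pos_of)
    lo, hi = EXCLUDED_TRACT
    free_positions = [
        p
        for p in ref.positions()
        if p not in motif_positions and not lo <= p <= hi
    ]

    out = []
    counter = 0
    for pop in sorted(clade_frequencies):
        freqs = clade_frequencies[pop]
        if not math.isclose(sum(freqs.values()), 1.0, abs_tol=1e-9):
            raise ValueError(f"frequencies for {pop} must sum to 1")
        n = n_per_population[pop]
        quotas = {c: f * n for c, f in freqs.items()}
        counts = {c: int(q) for c, q in quotas.items()}
        short = n - sum(counts.values())
        for c, _rem in sorted(
            quotas.items(), key=lambda kv: (kv[1] - int(kv[1]), kv[0]), reverse=True
        )[:short]:
            counts[c] += 1
        for clade in sorted(counts):
            for _ in range(counts[clade]):
                vs = [parse_variant_label(lab) for lab in sorted(folded[clade])]
                for _k in range(rng.poisson(private_rate)):
                    p = int(free_positions[rng.integers(len(free_positions))])
                    base = ref.base_at(p)
                    alt = _TRANSITION[base]
                    vs.append(Variant(p, "substitution", alt))
                sid = f"P{counter:04d}"
                counter += 1
                out.append((sid, pop, clade, tuple(sorted(set(vs)))))
    return out


# ---------------------------------------------------------------------------
# scenario presets


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    description: str
    model: DemographicModel | None
    config: SimulationConfig
    clade_frequencies: Mapping[str, Mapping[str, float]] | None = None
    n_per_population: Mapping[str, int] | None = None
    coordinates: Mapping[str, tuple[float, float]] | None = None
    expansion_years: float | None = None


def scenario_presets() -> dict[str, ScenarioPreset]:
    """Named study-shaped scenarios.

    * ``constant``: one constant-size population, theta = 5, n = 60.
    * ``expansion_8ka``: sudden expansion 8 ka ago (tau from the default
      calibration), 200-fold growth, n = 60.
    * ``north_south_cline``: six populations of 20 on a latitudinal
      gradient with clade frequencies shifting north to south.
    """
    cal = DEFAULT_CALIBRATION
    tau_8ka = 2.0 * cal.L * cal.mu_site_year * 8000.0
    presets = {
        "constant": ScenarioPreset(
            name="constant",
            description="constant-size neutral control, theta=5, n=60",
            model=DemographicModel(kind="constant", theta=5.0),
            config=SimulationConfig(n=60),
        ),
        "expansion_8ka": ScenarioPreset(
            name="expansion_8ka",
            description="sudden expansion 8 ka ago, theta 0.5 -> 100, n=60",
            model=DemographicModel(
                kind="sudden_expansion", tau=tau_8ka, theta0=0.5, theta1=100.0
            ),
            config=SimulationConfig(n=60),
            expansion_years=8000.0,
        ),
        "north_south_cline": ScenarioPreset(
            name="north_south_cline",
            description=(
                "six populations, 20 samples each, on a 17-34 degree-south "
                "gradient; southern clade L0d2a gives way to northern L0d1c"
            ),
            model=None,
            config=SimulationConfig(n=120),
            clade_frequencies={
                f"P{i}": {"L0d2a": 0.9 - 0.15 * i, "L0d1c": 0.1 + 0.15 * i}
                for i in range(6)
            },
            n_per_population={f"P{i}": 20 for i in range(6)},
            coordinates={
                f"P{i}": (-34.0 + 3.4 * i, 20.0 + 1.5 * i) for i in range(6)
            },
        ),
    }
    return presets


def get_preset(name: str) -> ScenarioPreset:
    presets = scenario_presets()
    if name not in presets:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    return presets[name]


def run_preset(name: str, seed: int | None = None):
    """Run a preset end to end; returns (sequences-or-records, truth-or-None)."""
    preset = get_preset(name)
    cfg = preset.config
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if preset.model is not None:
        return simulate_coalescent(preset.model, cfg)
    from .haplogroups import load_default_tree

    records = seed_motifs(
        load_default_tree(),
        preset.clade_frequencies,
        preset.n_per_population,
        private_rate=0.5,
        seed=cfg.seed,
        reference=cfg.reference,
    )
    return records, None
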