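# Methods

This note documents the models, conventions and numerical choices behind
`mitopop`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates, variants and normalization

All positions are 1-based rCRS coordinates. A haplotype is the set of
its differences from the reference over HVS-I (15997–16569) and HVS-II
(57–607), 1124 bp combined. Variant labels follow field notation:
`16223T` (substitution), `16278C!` (back-mutation to the reference
state), `498delC`, `523insCA`.

Variant calling applies three normalization rules, all on by default and
individually switchable in `AlignmentPolicy`:

1. variation in the HVS-II 303–315 poly-C tract is not called;
2. insertions in the 568–573 poly-C tract are recorded as a single
   `573insC` regardless of how many Cs were inserted;
3. substitution-vs-indel ambiguity inside 16184–16193 resolves to
   substitutions whenever the read carries the same number of bases as
   the reference across the tract.

Indels are a fifth character state: each indel event contributes weight
1 to haplotype identity and pairwise distances. Indels are placed
canonically at the rightmost position of a homopolymer run, so a C
inserted anywhere in a C-tract is the same variant. The 523 "AC"
repeat is treated as a single motif event (`523insCA`/`523delCA`);
copy-number beyond ±1 collapses to ±1 by default because this repeat is
too unstable to carry phylogenetic signal. Unknown bases (N) suppress
calls at their positions and flag the profile as partially observed.

Alignment is an affine-gap global alignment per segment (match +1,
mismatch −1, gap open −4, extend −1, read end-gaps free), with segment
auto-detection by score and rejection below 80 % identity or 80 %
coverage. The contract is the resulting variant calls, not the specific
aligner.

### The synthetic reference

The package does not bundle the rCRS sequence itself; the shipped
default reference is a deterministic **synthetic** stand-in: a
pseudo-random C-rich sequence carrying the real structural features the
rules above depend on (poly-C tracts with their interruptions, the CA
repeat, pinned bases at every motif position so each motif label names a
non-reference state). Every statistic in the package is
reference-relative, so nothing downstream depends on the stand-in's base
identities; analyses of real data should construct `ReferenceSegments`
from the true rCRS segments.

## Haplogroup classification

The motif tree is data (`data/motifs.tsv`): clade, parent, defining
variant labels. The shipped table encodes the revised L0d/L0k topology —
new clades L0d2d (`188G` under the `16212G` node), L0dx (`16179T` +
`523insCA`) and L0d3a (`16129A`, `16274G!`, `16399G`); `16300G` and
`523delCA` removed from L0d3, `16239T` from L0d1b, `198T` from L0d2a;
the L0d1,2 core defined by `498delC` + `16278C!`; L0d1 separated from
L0d2 by `523insCA`; L0d2c carrying only `294A`. Clades whose
control-region motifs that revision does not print (L0d1a, L0d1c,
L0d1c1, L0k1, the macro-haplogroup placeholders) ship as *curated
placeholders*, flagged `curated` in the table, and are meant to be
edited for production use — the classifier is entirely data-driven.

A clade's expected variant set is its **folded path**: walking from the
root, forward motifs add variants and reversion motifs (`!`) remove the
earlier variant at that position. Assignment scores every clade by
(matched − missing) over its folded set, requires at least one match and
at most `tolerance` (default 1) missing, and breaks score ties by depth;
remaining ties are flagged ambiguous rather than silently broken. Two
deliberate choices:

* a haplotype that *retains* a variant the candidate's path has reverted
  counts that as a mismatch — an L0d3 haplotype still carrying `16278T`
  must not match the L0d1,2 core, whose definition is precisely the
  back-mutation;
* reversions are never required as positive evidence (absence of a
  variant is weak evidence), so partially observed haplotypes are not
  over-penalized.

`523insCA` motifs match on the presence of any CA-repeat insertion
regardless of copy number. For L0d2d-style "absence" definitions, the
absence of sibling motifs is enforced only through the scoring (the
sibling with its motif present always outscores L0d2d), i.e. only over
observed positions.

## Diversity and neutrality

* Hd = n/(n−1)(1 − Σp²) (unbiased); π = mean pairwise difference per
  site over all unordered pairs; θ_S = S/Σ_{i<n} 1/i per locus and per
  site; Ne = θ_locus/(2·L·μ·g).
* A *segregating site* is a variant label carried by some but not all
  sampled sequences; with the fifth-state rule two derived states at one
  position count as two labels, keeping S consistent with the pairwise
  distance.
* The effective length L for per-site statistics is a parameter
  (default the calibration's 1124); per-group effective lengths may be
  passed when sites are masked.
* Tajima's D follows its original variance decomposition; D = 0 exactly
  when the mean pairwise difference equals S/a1.
* Fu's Fs = ln(S′/(1−S′)) with S′ = P(K ≥ K_obs | θ̂ = k̂) under the
  Ewens sampling formula. Stirling numbers of the first kind are
  computed by a log-space recursion, stable to n ≈ several hundred.
* R2 uses folded singletons (minority state carried by exactly one
  sequence), U_i per sequence, R2 = sqrt(Σ(U_i − k/2)²/n)/S.
* p-values are Monte-Carlo, conditioning on the observed S: a Hudson
  constant-size coalescent genealogy is drawn and exactly S mutations
  are placed on branches proportionally to length
  ("fixed-S"/Hudson-style conditioning; conditioning on θ̂ is the main
  alternative and can be emulated by passing a custom null). The growth
  direction is the **low tail for all three statistics** — D and Fs
  negative, R2 *small*. Published prose sometimes describes "positive"
  R2 values as significant; this package follows the statistic's source
  convention (small R2 indicates growth) and exposes the tail as an
  option. p = (#{as-or-more-extreme} + 1)/(n_sims + 1); n_sims ≥ 1000 is
  enforced unless a precomputed null table is supplied, which groups
  sharing (n, S) should reuse.

## Mismatch distributions

The observed distribution counts all unordered pairs (within-haplotype
pairs contribute difference 0). The sudden-expansion model assumes a
population at θ0 that jumped to θ1 at τ/2 mutation-time units ago
(τ = 2ut). The expected pairwise-difference distribution is the sum of a
truncated-gamma term for pairs coalescing after the expansion and a
Poisson(τ)-convolved equilibrium term for older pairs; the
implementation is closed-form, verified against numerical quadrature of
the integral form, and normalizes to 1 within 1e-6 over its truncation
range.

Fitting minimizes the sum of squared deviations (SSD) between observed
and expected relative frequencies with a Nelder-Mead simplex in
log-parameter space, started from the method of moments (τ₀ = observed
mean pairwise differences, small θ0, large θ1); θ1 is capped at 1e5 to
emulate the θ1 → ∞ convention. The SSD and raggedness p-values come from
a parametric bootstrap: simulate coalescent samples under the fitted
parameters (infinite sites, step demography in mutation time), refit
each, and report the fraction with SSD (raggedness) at least the
observed. Bootstrap replicates default to 1000; the bootstrap also
yields a percentile CI for τ. Raggedness is Harpending's
r = Σ(x_i − x_{i−1})² with a trailing zero class. Expansion ages are
years = τ · years-per-mutation / 2.

## ρ dating

ρ is the multiplicity-weighted mean mutation count from a clade's root
to its sampled haplotypes (sampled internal nodes count; inferred
ancestors do not). σ follows Saillard's recursion
σ² = Σ_edges (n_e/n)²·m_e, which reduces to sqrt(Σm)/n on a star.
Coalescence mode roots at the clade MRCA; divergence mode roots at the
MRCA's parent, adding the stem mutations to every path (and the full
stem weight to σ²). Calendar conversion is linear:
years = ρ/(L·μ). The default calibration (μ = 1×10⁻⁷/site/year,
L = 1124, g = 25 y) was chosen so that a single rate reproduces both the
ρ→years and θ→Ne conversions of the reference workflow; it is fully
overridable, and alternative published control-region rates can be
passed as `RateCalibration` instances. Reticulated genealogies are
resolved to a BFS shortest-path spanning tree (lexicographic
tie-breaks) before dating; the resolution is deterministic and should be
reported with the estimate.

## Median-joining networks

Distances are weighted symmetric differences of variant sets (a metric).
The ε-relaxed minimum spanning network includes a link when its distance
is within ε of its Kruskal merge level (ε = 0 gives exactly the union of
all minimum spanning trees). Median generation takes each triplet with
at least two MSN links, adds the majority-consensus (quasi-median)
vector if new, and iterates to a fixpoint (10⁴ median guard); obsolete
medians — unsampled nodes of degree ≤ 2 — are pruned. All iteration
orders and tie-breaks are lexicographic in the haplotype key, so output
is invariant to input permutation. Optional position weights ship with a
profile down-weighting the hypermutable sites 16189, 523 and 573 at 0.5;
default weights are 1.0 and ε = 0 (declared defaults, not inferred from
any particular study). Rooting attaches an outgroup at its nearest node
and orients edges away from the root; edges on cycles cannot be oriented
and are flagged ambiguous. Star patterns (centers with ≥ k leaf
neighbors, default 4) summarize expansion signatures.

## Population structure

ΦST between two populations is the AMOVA variance decomposition of
squared inter-haplotype distances (the fifth-state variant-count
distance by default, 0/1 identity for frequency-based Fst):
σ²_a/(σ²_a + σ²_w) with the standard two-level sums of squares and
n′ = (N − Σn_p²/N)/(P−1). Negative estimates — which arise for
identical or nearly identical populations because MS_among < MS_within —
are reported as computed, not truncated. Populations with n < 10 are
excluded by default (overridable). UPGMA uses average linkage
(scipy) serialized as newick via scikit-bio, with negative input
distances clamped to zero with a warning. Geographic distances are
haversine great circles on a 6371-km sphere. The Mantel test correlates
upper triangles, permuting one matrix's rows and columns jointly;
p = (hits + 1)/(N + 1), with an exact-enumeration mode for small
matrices. Frequency surfaces use inverse-distance weighting (power 2)
on great-circle distances, exact at sample coordinates and clipped to
[0, 1]. Population coordinates are user-supplied metadata.

## Synthetic data

The generator works in **mutation-time units**: per-branch mutation rate
1, k-lineage coalescence rate k(k−1)/θ, so branch lengths are expected
mutation counts, a clade's depth is its TMRCA in mutations, and the
sudden-expansion change-point sits at τ/2. Demographies: constant(θ),
sudden_expansion(τ, θ0, θ1), exponential growth (inverse-transform
waiting times). Mutations are finite-sites: uniform position outside the
excluded 303–315 tract, transition with probability κ/(κ+1) (κ default
5.6), else a random transversion, with a 2 % indel channel toggling
fifth-state events — so reversions and recurrent hits arise naturally
and exercise the normalization rules. The full genealogy, TMRCA, event
tallies and per-tip variant sets are recorded as ground truth. Presets:
`constant` (θ = 5, n = 60), `expansion_8ka` (τ from the default
calibration at 8 ka, θ 0.5 → 100, n = 60, chosen to mirror a
well-supported Holocene expansion), and `north_south_cline` (six
populations of 20 on a latitudinal gradient with clade frequencies
shifting 0.9 → 0.15). All randomness flows from one seeded generator;
outputs are byte-identical across runs with the same seed.

What the generator does **not** emulate: sequencing error and phantom
mutations, rate heterogeneity among sites beyond the Ts/Tv bias,
heteroplasmy, population admixture with migration matrices, and
selection. Passing tests therefore demonstrate estimator correctness
under the stated models, not robustness to real-world artifacts.

## Test design and problem sizes

Unit tests pin every closed-form example to an independently computed
value (enumeration, quadrature, hand AMOVA, Chinese-restaurant
recursion, Prüfer-sequence spanning-tree enumeration, dendropy's
population-genetic statistics as an external cross-check). The
end-to-end checks run at sizes chosen to finish in seconds to a few
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted bounds: neutrality-test calibration uses 150 datasets of n = 25
against 1000-replicate fixed-S nulls cached per (n, S); τ recovery uses
the expansion_8ka preset with 200 bootstrap replicates; ρ unbiasedness
uses 500 replicates of n = 12. Determinism is asserted by re-running
seeded paths.

## Known limitations

* The assignment scorer is motif-greedy; haplotypes equidistant between
  sibling clades are flagged ambiguous rather than resolved by coding
  region information (supply macro-haplogroup calls to restrict the
  subtree).
* Fixed-S conditioning is the only built-in null for neutrality
  p-values; θ̂-conditioned nulls must be supplied by the caller.
* The mismatch bootstrap refits with the same optimizer it tests, so
  optimizer failure modes (flat SSD surfaces at very small τ) affect
  both sides; `converged` flags best-so-far results.
* Median-joining is an approximation to the full quasi-median closure;
  extremely reticulate data may retain medians a maximum-parsimony
  analysis would not.
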