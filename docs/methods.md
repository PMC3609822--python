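# Methods

## Scope and data model

The package analyses a single non-recombining maternal locus. Its unit of
observation is the aligned sequence of one sample; identical sequences are
one *haplotype*. Identity is strict, site by site, gaps included; `N`
matches only itself, so two samples differing only at an ambiguous site
remain distinct haplotypes. This is deliberately conservative: ambiguity
resolution belongs upstream (base calling, alignment, block selection), and
the pipeline consumes a finished alignment. Haplotype ids `H001…` are
assigned by first appearance, which makes every downstream artifact
deterministic for a given input file; published names can be attached via a
user mapping, since they are not computable.

## Distances

Pairwise difference counts use *pairwise deletion*: each pair is compared
over the sites where both carry an unambiguous base, and the per-pair
comparable-site counts are kept alongside the matrix. Complete deletion
would discard every site with a single gapped sequence, which for
control-region data wastes most of the signal. A pair with no comparable
sites yields NaN with a warning (an error in strict mode).

The TN93 distance separates the two transition classes (A↔G, C↔T) from
transversions with base frequencies estimated once from the pooled
alignment. The implementation reproduces `ape::dist.dna(model="TN93",
pairwise.deletion=TRUE)` to 10 significant digits on a fixture whose values
are pinned in the tests; saturation (a non-positive logarithm argument)
yields NaN with a warning rather than a fabricated value. Per-pair frequency
estimation is available as an option but is not the default, because the
pooled estimator is the standard one and keeps the matrix internally
consistent.

Clade-level summaries report, per clade, the mean pairwise distance within
(undefined for singletons), between each clade pair, and the net
(corrected) distance `between − (within_i + within_j)/2`. The headline
mean ± sd aggregates over the clades (within) and over the unordered clade
pairs (between) — i.e. at the granularity of the clade-by-clade table, not
of the raw haplotype pairs. Both raw-count and TN93 variants are supported;
raw counts are the default for "number of pairwise differences" style
quantities, TN93 for tree building.

## Trees, bootstrap, clades

Neighbor joining is the standard Saitou–Nei agglomeration; UPGMA is
average-linkage with merge heights halved. Both break ties by the
lexicographically smallest pair of cluster representatives (the smallest
leaf label in each cluster), so the topology is a pure function of the
distance matrix. Negative NJ branch lengths are retained internally and
clamped to zero only when writing newick.

Bootstrap support resamples alignment columns with replacement, rebuilds
the tree per replicate, and scores each internal bipartition of the
point-estimate tree by the percentage of replicates containing it. Two
numerical choices matter:

* A bipartition counts as present in a replicate only if its branch has
  positive length. NJ resolves even a completely uninformative (all-zero)
  matrix into some topology via tie-breaking; without the length filter,
  identical sequences would earn 100% support for arbitrary structure.
* Replicates in which some pair has no comparable sites (or TN93
  saturates) are skipped and counted in the output tree's
  `bootstrap_skipped` attribute.

Collapsing contracts every internal branch below the support threshold
(default 70%), leaving a multifurcating tree. Clade (haplogroup) extraction
is automated as *maximal supported rooted clusters*: the collapsed tree is
rooted at its backbone centre — the internal node from which the largest
number of supported clusters emanate, ties resolved by preorder — and the
first cluster on each root-to-leaf path whose bipartition keeps ≥ 70%
support becomes a clade; uncovered leaves become singletons. Rooting at the
backbone centre rather than the midpoint avoids two failure modes observed
in development: a midpoint landing inside a deep clade's stem would offer
the giant complement side as a single "clade", and midpoint rooting of
degenerate (star-like or equal-length) trees is ill-conditioned. When the
chosen root is a bifurcation, the larger child is treated as the ancestral
side and descended into whenever it resolves into two or more supported
clusters, so one supported bipartition is not consumed twice. Clade labels
`C1, C2, …` order clusters by size then smallest member; field names (A1,
B2, …) attach via a user mapping.

## Diversity, F_ST, AMOVA

For a population with haplotype frequencies `p_i` over `n` samples:
haplotype diversity `h = n/(n−1)(1 − Σp_i²)` with Nei's sampling variance;
mean pairwise differences Π as the mean inter-haplotype distance over the
`n(n−1)/2` sample pairs; nucleotide diversity π = Π/L with the standard
total variance `V(π) = ((n+1)/(3(n−1)L))π + (2(n²+n+3)/(9n(n−1)))π²` and
`sd(Π) = sd(π)·L`. Polymorphic sites are the alignment columns with two or
more distinct unambiguous bases among the population's haplotypes.

AMOVA follows the classic sums-of-squared-distances decomposition for
haplotype data, in which the raw pairwise difference count *is* the squared
Euclidean distance: `SSD(total) = (1/N)Σ_{i<j}δ²`, within-stratum terms
analogously, variance components by method of moments with the
unequal-sample-size coefficient `n̄ = (N − Σn_g²/N)/(P−1)`, and
`Φ_ST = σ²_a/(σ²_a+σ²_w)`. Pairwise F_ST is exactly the two-stratum case,
so a single code path (validated against an independent brute-force
enumeration over individuals at 1e−9) serves both. The permutation test
shuffles individuals between the two populations of the pair only —
matching the pairwise null — and reports `p = (#{Φ* ≥ Φ} + 1)/(n_perm+1)`;
permutation p-values are verified to be uniform under a panmictic null.
Negative F_ST estimates are retained, in tables and in regressions.

Net population distance uses frequency-weighted averages throughout:
`d_net(X,Y) = Π_XY − (Π_XX + Π_YY)/2` with `Π_XX = Σ_{ij} p_i p_j d_ij`
(denominator n², not n(n−1)): with this form two identically composed
populations are at distance exactly zero, which is the invariant a
"corrected" distance should satisfy. The UPGMA population tree is built on
this matrix by default; the F_ST matrix can be substituted.

## Geographic indices

Population centres are arithmetic means of the sample coordinates (a
small-extent approximation appropriate at basin scale). Straight distance
is the haversine great circle with mean Earth radius 6371 km. Crossing
counts and detours treat rivers as open polylines with a width class;
only `large` rivers (those at least as wide as the reference tributary —
a map attribute supplied by the user, since "wide enough to block
movement" is not a computable property) act as obstacles.

Crossings are counted as transversal intersections of the straight segment
with each large-river polyline in a local equirectangular projection about
the pair midpoint; a tangential touch at a shared vertex counts once, and
an endpoint lying exactly on a large river is an error (the count is
ill-posed). The implementation is shapely's segment–polyline intersection,
checked against a from-scratch parametric enumeration on randomized
fixtures.

The detoured distance formalizes "go around the headwater": it is the
shortest polygonal path from a to b whose segments cross no large river.
Since rivers are open polylines, paths may round their termini; candidate
waypoints are points offset 100 m beyond every large-river vertex in eight
compass directions, and the shortest path is found by Dijkstra on the
visibility graph over {a, b, waypoints}. Unobstructed pairs return the
haversine distance exactly; infeasible configurations (a closed obstacle
ring) return infinity. The planar approximation can undershoot the
geodesic by a sliver, so the result is floored at the straight distance,
keeping `detoured ≥ straight` a hard invariant. Against a closed-form
around-the-endpoint oracle for a single straight river the route length
agrees within 1%.

## Correlations and model selection

Pearson r is tested with `t = r√((n−2)/(1−r²))` two-sided. The KS normality
check of the F_ST values is the one-sample plug-in test against a normal
with the sample mean and sd (the estimated-parameter Lilliefors correction
is available but not default, matching common practice of reporting the
plain test for this diagnostic).

The barrier model is ordinary least squares (a Gaussian-identity GLM) of
pairwise F_ST on any subset of {straight, detoured, crossings}, with
per-coefficient t and p and the effect sign. AIC uses the full Gaussian
log-likelihood including the variance parameter,
`AIC = n·ln(2π·RSS/n) + n + 2(k+2)` for k predictors — verified equal to
R's `AIC` on a gaussian `glm` to 1e−4 on a pinned fixture — which is what
makes small-RSS fits come out negative. `model_comparison` ranks the three
single-factor fits and the straight+crossings two-factor fit, optionally
excluding one population's pairs (the leave-one-out sensitivity used to
probe a single anomalous site). Collinear predictor sets are rejected with
a condition-number diagnostic.

One caveat is inherent to the design: the 21 pairwise rows of a
seven-population distance table are not independent observations. The
package reproduces the conventional Pearson/GLM treatment of such tables
and additionally offers a Mantel permutation test (permuting population
labels) as a clearly labelled extension; the headline statistics are the
conventional ones.

## Synthetic data

The generator is a phenomenological stand-in for coalescent migration
models, chosen for speed and for having closed-form expectations.

* **Sequences.** A uniform random root; each of `n_clades` (default 6)
  clade ancestors adds `Poisson(λ_B)` substitutions, each haplotype
  (default 9 per clade, 54 total) adds `Poisson(λ_W)` more; substitutions
  pick a uniform different base, so expected between-clade differences are
  ≈ 2(λ_B+λ_W) and within-clade ≈ 2λ_W. Defaults λ_B = 14.0, λ_W = 3.9
  emulate the magnitudes of a deeply structured control-region survey
  (between ≈ 36, within ≈ 7.8, ratio ≈ 4.6) on L = 1121 sites. Every
  clade draws all of its substitutions from its own disjoint block of
  sites. This makes between-clade relationships exactly star-additive:
  without it, chance cross-clade homoplasy is an unopposed, resampling-
  stable signal, and the site bootstrap awards arbitrary clade pairs high
  support (the bootstrap measures signal strength, not signal truth).
  Within a clade homoplasy is allowed. A TN93-biased mutation option
  exists for distance-estimator tests.
* **Geography.** Seven populations at basin-like coordinates with the
  survey's sample sizes (16, 7, 35, 7, 37, 18, 16; 136 total) and a
  stylised river network. The effective distance between populations is
  `d_eff = straight + β·crossings`, with β in km per large-river crossing
  (β = 0 by default: rivers present but genetically inert).
* **Frequencies.** Each clade is seeded at a random home population (the
  isolated-population scenario pins exactly one clade to the isolated
  site); haplotype h's weight in population p is `exp(−d_eff(p,
  home(h))/σ)`, and p's frequency vector is Dirichlet with mean
  proportional to those weights and concentration κ (default 100). As
  σ → ∞ with β = 0 all populations share one near-uniform frequency
  vector (mean pairwise Φ_ST ≈ 0.007 over seeds — the panmixia limit);
  the default σ = 80 km produces majority locality-specific haplotypes
  and strong structure, emulating the survey's 83% locality specificity
  at the cost of saturating F_ST between distant pairs.
* **Samples.** Multinomial draws per population, random sexes
  (0.4/0.4/0.2 male/female/unknown), coordinates jittered N(0, 0.12°)
  about the population centre; files are written in exactly the dialects
  the readers consume, and all randomness flows from one seed through
  named SeedSequence spawns.

### Scenario configurations

The three recovery scenarios used in the acceptance suite are study
designs of their own, not the default conditions:

* `ibd_config` — β = 0, σ = 300 km ("moderate": F_ST still responsive at
  the longest inter-population distances), and a dedicated
  *identifiability* river layout whose large rivers cut short and medium
  pairs and leave the far-eastern population unwalled. With the
  study-like map the detour inflation loads on exactly the farthest
  pairs, where the saturating F_ST response bends above a straight-line
  fit, and the (spurious) detoured model wins a third of replicates no
  matter how small the noise — a property of that landscape's collinear
  predictors, not of the estimator. Decorrelating the indices is the
  standard remedy, and with it the straight-distance model attains the
  lowest single-factor AIC in ≈94% of replicates.
* `barrier_config` — σ = 300 km, β = 1000 km per crossing; the crossings
  coefficient in the straight+crossings fit is positive and significant
  in ≈92% of replicates.
* `isolated_config` — default σ = 80 km, β = 1500, one clade pinned to
  the isolated population; that population shares no haplotypes and its
  haplotypes form exactly one exclusive clade in ≈100% of seeds.

### What passing synthetic tests does and does not show

The generator reproduces the *structure* of the real study (clade depth,
locality clustering, sample sizes, a river-crossed landscape) but not its
demographic history: there is no coalescent genealogy, no migration–drift
equilibrium, no time axis, and frequencies are exchangeable Dirichlet
draws rather than the outcome of gene flow. Passing recovery tests
therefore demonstrates that the estimators and the model-selection chain
extract the right signal when the generating process matches their
assumptions — not that those assumptions hold for any particular river
basin. Numbers computed on synthetic data (AMOVA percentages, F_ST
magnitudes, specificity proportions) are properties of the generator's
settings, not reproductions of the survey's values, which depend on
unpublished per-sample data and manual GIS measurements.

## Problem sizes and determinism

Default test and acceptance runs use 100–200 bootstrap replicates, 100
replicates per recovery scenario (50 for the isolated scenario, which
re-runs the bootstrap each time), and 1023-permutation F_ST tests — sizes
chosen so the full suite completes in a few minutes on one CPU while
keeping Monte-Carlo error well inside the asserted margins. Every
stochastic stage takes an explicit seed; identical seeds give
byte-identical output files, and the pipeline's run log records the seed
and input hashes for audit.

## Known limitations

* Support values come from the NJ bootstrap alone; corroboration by ML/MP
  replication is out of scope, so collapse decisions can differ from a
  multi-method consensus.
* The bootstrap's zero-length filter is slightly conservative: a true
  bipartition realised with zero branch length in a replicate is not
  counted.
* The sd printed for Π follows `sd(π)·L` under the variance form above;
  software lineages differ in which total-variance estimator they print,
  and alternative conventions are deliberately not chased.
* Detour routing assumes rivers are passable only beyond their mapped
  termini; braided channels, bridges/fords and seasonal width changes are
  not modelled.
* GLM inference treats pairwise rows as independent; use the Mantel
  option when that assumption matters.
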