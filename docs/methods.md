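# Methods

This note documents the models, numerical choices, and synthetic-data
design behind `divdensity`, including the places where the design was
genuinely open and what the package chose.

## Dated trees and clade slicing

Trees are rooted, binary or multifurcating, with branch lengths in Myr.
Ages are computed root-down and measured backward from the present; the
ultrametricity check allows a relative tolerance (default 10⁻⁶ of the root
age, configurable) because rate-smoothed chronograms are never exactly
ultrametric. Within-tolerance tips are snapped to age 0.

Slicing at a cutoff `c` selects every branch with
`parent.age > c ≥ child.age` (half-open, so a node exactly at the cutoff
falls below the cut — a deterministic tie-break). Each crossing branch
with ≥ 2 descendant tips becomes an *unnamed clade*; single-tip lineages
are reported separately and excluded from regressions. A clade's stem age
is the age of the parent node of its crossing branch; `stem_age_mode="cutoff"`
is available for sensitivity analyses since the stem-age convention for
sliced lineages is not uniquely determined. No correction for unsampled
species is applied: unnamed clades have no taxonomic identity, so their
true richness is unknowable by construction, and the rate metric is used
comparatively across clades of the same tree.

Tips missing trait data are ignored inside a clade's median; a clade left
with fewer than two trait-bearing tips keeps its species count but is
flagged; a clade with none is dropped with a warning.

## The bounded-landscape trait models

The general model is an Itô diffusion on a trait interval,
`dX = −(σ²/2)V′(X)dt + σ dW`, with stationary density ∝ exp(−V). The
potential is a polynomial `a·u⁴ + b·u² + c·u` evaluated on the grid axis
rescaled to [−1.5, 1.5]; the rescaling keeps coefficient magnitudes
comparable across grids, so fitted `a, b, c` are only interpretable
together with the grid. Seven members are fitted: BM (2 free parameters:
σ², root state), OU (3: σ², α, θ, root at θ), FPK (4: σ² and the quartic
potential, bounds placed 10 trait SD outside the data, i.e. effectively
unbounded), and the bounded BBMV4 (4), BBMV2 (3, a = 0), BBMV1 (2,
a = b = 0), BBM (1, flat potential). Default bounded grid: 100 points on
[log₁₀ 0.01, log₁₀ 50] — 1 cm to 50 m, the plausible span for the kind of
plant data this targets. Bounds are fixed, not estimated, and not counted
as parameters; the root is integrated against a prior, not counted.

### Discretization

The diffusion is discretized as a birth–death chain on the grid with
nearest-neighbour rates `q(i→j) = σ²/(2h²)·exp(−(V_j − V_i)/2)`. This
scheme satisfies detailed balance with π ∝ exp(−V) *exactly* on the grid
(so the stationary density of the chain is the macroevolutionary landscape
with no discretization error) and recovers the Fokker–Planck drift to
O(h). Reflecting bounds are automatic — no rates leave the interval. The
generator is symmetrized by D = diag(π^½) into a symmetric tridiagonal
matrix with constant off-diagonal σ²/(2h²), so each likelihood evaluation
needs one `eigh_tridiagonal` and branch propagation is two matrix–vector
products per edge.

`V − min(V)` is capped at 60 before exponentiation: cells above the cap
hold stationary mass < 10⁻²⁶, while an uncapped potential would amplify
eigendecomposition round-off through the D⁻¹ factor.

### Likelihood

Felsenstein pruning over grid cells. Tip observations place unit mass on
the nearest cell by default; `tip_mapping="linear"` splits mass between
the two flanking cells (first-moment exact), which roughly squares the
order of the tip-placement error and is what the closed-form comparisons
use. Partial likelihoods are rescaled by their maximum per node. The root
is integrated against the model's stationary density (consistent with the
landscape interpretation) or a flat prior (`root_prior="flat"`); both are
exposed because the choice matters for root-state estimates near a bound.
The grid mass likelihood is converted to a continuous density
(− n_tips·log h) so grid models, BM, and OU are AIC-comparable.

Validation: with a flat potential and wide bounds the grid log-likelihood
matches the analytic Brownian likelihood (root integrated over the same
interval) to < 0.05 on 10-tip trees at 200 grid points; with a Gaussian
potential matched to (α, θ) it reproduces the stationary-root OU
likelihood to < 0.1. Tested in `tests/test_acceptance.py`.

### Fitting

BM is closed-form GLS; OU profiles (σ², θ) over a 1-D bounded search in
log α. Grid models maximize over (log σ², active coefficients) with
L-BFGS-B from Latin-hypercube starts (default 5) spanning ±3 log units of
σ² around the BM estimate and ±8 on the coefficients; hard bounds ±20 on
coefficients. `fit_all_models` additionally warm-starts each bounded model
from the optimum of the model nested inside it, which guarantees the
nesting chain logL(BBMV4) ≥ logL(BBMV2) ≥ logL(BBMV1) ≥ logL(BBM) up to
optimizer tolerance. Convergence tolerance 10⁻¹⁰ on the objective;
`converged=False` flags a fit in which no start finished finite.

## Range areas

Occurrence cleaning: (1) drop records outside the study-region polygon
(boundary points kept); (2) drop records whose locality text contains
"botanical" or "garden", case-insensitive substring — a deliberately crude
but exactly reproducible rule ("Gardenia" is a documented false positive).
The two filters commute.

Hull areas use a Lambert cylindrical equal-area projection on a sphere
(R = 6371 km) centered on the points' mean longitude, then a planar convex
hull. The projection is exactly area-preserving; the only approximation is
straight chords for hull edges, < 0.5% for a 1° square (checked against
the spherical rectangle formula R²Δλ·Δsinφ). Exact duplicates (10⁻⁶ °) are
dropped before hulling; < 3 distinct or collinear points give area 0 and
the clade is flagged out of density regressions. Hulls are not
antimeridian-aware (inputs spanning > 180° of longitude warn): the intended
study regions sit far from ±180°. The projection/ellipsoid choice is
logged with results because A enters the headline metric; a geodesic
alternative would differ by ≲ 0.3% at these extents.

## Metrics

`rate = log(n)/t_stem`, `density = log(n)/√A`, plus the comparison
variants `n/A`, `log(n)/A`, `log(n)/log(A)`. Logs are natural by default;
base 10 is available and applied to both metrics at once so rate–density
comparisons stay coherent (the choice rescales both by 1/ln 10 and is
irrelevant to correlations and slope signs). Monotypic clades have
rate = density = 0; A ≤ 0 or t ≤ 0 raise, with the affected clades
excluded upstream.

## Phylogenetic regressions

For each tree × cutoff, clades are collapsed to single tips on the
*backbone* phylogeny: branch lengths above the cut are preserved, each
clade hangs from its crossing branch ending at the cutoff, singleton
lineages are removed (with their unifurcations suppressed), and the whole
tree is shifted so tips sit at age 0. Clade trait medians are treated as
tip observations at the cut — the mapping of clade summaries onto backbone
positions is not uniquely determined, and this convention (rather than,
say, stem-node placement) is the one the covariance uses; it is switchable
in principle via the slicing conventions above.

PGLS estimates Pagel's λ by profile maximum likelihood on a 101-point grid
over [0, 1] plus a local bounded refine (boundary optima reported as
exactly 0 or 1), then solves the GLS given λ̂. Slope standard errors and
the 95% CI use a t distribution with n − 2 df; a slope is "significant"
when that CI excludes zero. λ = 0 reproduces OLS to 10⁻⁸ and λ = 1 the
full-Brownian GLS (both tested). Sweeps skip tree × cutoff cells with
fewer than 3 usable clades.

**Known limitation — test calibration.** With ~20 clades per regression
and a response that spans an order of magnitude across clades (the density
of a 2-species clade with a tiny hull vs. a deep clade with a large one),
the residual variance is heterogeneous and λ̂ is noisy; the null rejection
rate of the slope test is ~3% at shallow cutoffs (many clades) but rises
to ~9–12% at deep cutoffs (few clades), ~8% overall on null synthetic
data. Consumers should read borderline slope p-values at deep cutoffs
conservatively; the negative-density result in coupled data is far from
this margin (every fit negative, most CIs excluding zero).

The decoupling summary is the Pearson correlation (Spearman behind a flag)
between rate and density across clades, per tree × cutoff, with the
fraction of comparisons non-significant at 5%.

Trait-distribution shape is summarized by sample skewness `g1` and the
D'Agostino z-transform skewness test (n ≥ 8).

## Spatial simulator

Individuals of one clade live on a W×H grid of local communities with
carrying capacity K. Per step: (1) every occupied cell is resampled to
exactly K offspring, species drawn multinomially by local abundance;
(2) each individual migrates with probability m to a uniform 4-neighbour
cell, edge moves cancelled; (3) each extant species speciates with
probability s — *point mutation* converts the individuals of one random
occupied cell, *vicariance* splits the occupied cells along a random
axis-aligned line and converts one side; (4) species at zero individuals
are extinct (extinction is emergent; there is no extinction parameter).
These update rules are this package's concretization of a
qualitative scheme; they are isolated in `spacesim` so alternates can be
swapped. Two deliberate refinements:

- A species occupying a single cell skips speciation in both modes.
  Speciation here means subdivision of a range; a "point mutation" of a
  1-cell species would relabel the whole species rather than split
  anything, and vicariance is undefined on one cell. Without this guard
  the two modes differ structurally at high packing.
- Clade area is the convex hull of occupied cell *footprints* (the unit
  squares' corners), not cell centers: a fully occupied W×W grid then has
  area W² rather than (W−1)², removing a (W/(W−1))² bias that would
  contaminate the n/A variant across landscape sizes. The raw occupied
  cell count is also reported.

Default parameters (W = H = 5, K = 20, m = 0.02, s = 0.1, 1500 steps)
place the community at its drift–invasion *packing equilibrium*: dispersal
slow enough that species ranges stay at ~1–3 cells and runs long enough
that richness has plateaued. This regime was chosen deliberately: during
transient range expansion the two speciation modes produce structurally
different daughters (a vicariance daughter inherits half its parent's
range and survives; a point-mutation daughter holds one cell inside the
parent's range and usually drowns), so richness differs by mode roughly
tenfold and no metric is mode-insensitive. At packing equilibrium both
modes carve equivalent daughters, and the validation sweep shows the
claimed pattern: ln(n)/√A falls with migration rate, falls with landscape
area, rises with carrying capacity, and is mode-insensitive
(|standardized mean difference| < 0.2), while the raw ratio n/A fails to
track landscape size (|ρ| ≈ 0, n.s.) because richness there scales
linearly with area. The simulator grids are small and abstract; nothing
about their absolute scales maps onto km².

## Synthetic data

The generator produces, from one root seed: a birth–death tree conditioned
on the extant tip count (pendant edges extended by the waiting time to the
next event so the present falls strictly between events), rescaled to a
fixed crown age; a posterior-like set of trees with node ages jittered by
lognormal(0, sd) factors (topology fixed — topological uncertainty is
irrelevant to the slicing machinery being exercised); heights evolved on
the bounded landscape; and occurrence records.

Defaults emulate a mid-sized succulent radiation: 200 tips, crown age
29 Myr, birth 0.15 / death 0.05 Myr⁻¹, 100 posterior trees with 5% age
jitter, σ² = 0.06 (log₁₀ m)²/Myr on a landscape with its peak near 3 cm —
close enough to the 1 cm bound that simulated height distributions come
out right-skewed on the log scale (positive skew in ≥ 95% of seeds), the
shape real data of this kind show.

Occurrences: species centroids evolve as spatial Brownian motion along the
tree (60 km/√Myr, reflected into a southern-African-like lon/lat box), so
related species are geographically close and clade range areas carry
phylogenetic signal, as dispersal-limited biogeography produces. Each
species then gets Poisson(30)+3 points, bivariate normal with standard
deviation `15·height_m^γ` km (lognormal(0, 0.4) species-level scatter;
cos-latitude correction on longitude). γ = 1 (*coupled*) builds in the
mechanism under test — taller plants disperse farther, so short plants
have tighter ranges and higher densities; γ = 0 (*null*, with a 40 km
common dispersion) breaks the link and calibrates false-positive rates.
Uniform-iid centroids were rejected during design: they make a clade's
hull area a near-deterministic function of its species count, which
induces leverage-correlated heteroscedasticity and measurably inflates the
null slope test. Contamination appends garden-string records inside the
region (5%) and out-of-region records (2%) for the cleaning filters to
catch.

What the generator does *not* emulate: topological uncertainty, sampling
fractions varying across clades, spatially autocorrelated sampling effort,
coordinate error, taxonomic synonymy, and real coastline/range geometry.
Passing tests therefore show the machinery is correct and the effect is
recoverable under the assumed structure — not that any particular
empirical dataset will behave this way.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on trees of 5–60 tips and grids of 21–201
points. The heavier scientific checks use: 20 replicates of 200-tip trees
for landscape recovery (64-point grids, 4 models, 4 starts); 100
replicates for PGLS slope coverage; 100 null datasets × 3 cutoffs for
calibration; simulator sweeps of 15–20 replicates per level with 250 per
speciation mode. `scripts/acceptance.py` uses 150-tip datasets, 5
posterior trees, 40 null datasets, and simulator sweeps of 10 replicates
(80 per mode); these sizes were chosen so the whole script completes in a
few minutes on one CPU while keeping Monte-Carlo noise well inside the
margins of the effects reported.
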