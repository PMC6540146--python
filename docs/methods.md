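# Methods

This note documents the models, algorithms and design choices behind
`neighscale`: what the synthetic city emulates, how each built-environment
measure and statistical quantity is computed, and what the package's tests
do and do not establish about real data.

## The synthetic study region

The generator produces, from a seed, a study region resembling a suburban
New Zealand-style city system and a cohort recruited from contrasting
high- and low-walkability neighbourhoods.

**Street network.** A regular grid of nodes at `spacing` metres (default
112 m, i.e. two intersections per meshblock edge) with 4-neighbour edges.
A fraction `culdesac_rate` (default 0.15) of the interior edges is
removed, producing dead ends; removal is spatially clustered through a
smooth Gaussian random field so that cul-de-sac-rich, low-connectivity
pockets emerge rather than uniformly sprinkled gaps, and each removal is
guarded so the graph stays connected. A fraction `motorway_fraction`
(default 0.02) of the remaining edges is tagged as motorway, guarded so
the pedestrian subgraph stays connected after filtering.

**Administrative hierarchy.** Meshblocks are square cells of `mb_cell`
metres (default 224 m → 0.050 km², a typical urban meshblock area). They
aggregate into area units of ~5×5 cells and the area-unit grid splits
into quadrant cities (four where the grid allows), so every meshblock has
an area-unit parent and a city ancestor. Deprivation deciles (1–10) come
from a second smoothed field.

**Dwellings and zoning.** Each meshblock holds a centred residential
rectangle covering 50–90% of its area. Dwelling counts are Poisson with
mean `density × residential hectares`, where log-density is the sum of a
smooth spatial field (sd 0.35, Gaussian-filter σ = 2 cells) and
meshblock-local white noise (sd 0.5) around a regional target of 10
dwellings/ha. The local term matters: census meshblocks differ sharply
from their neighbours (observed urban ranges span roughly 1–80
dwellings/ha), and it is precisely this small-area noise that attenuates
meshblock-scale exposure measures relative to buffer-scale ones — the
mechanism behind scale-dependent detection. Without it, exposures at all
seven definitions correlate above 0.9 and the scale effect all but
disappears.

**Walkability classes and study neighbourhoods.** The true walkability
index used in such studies combines dwelling density, connectivity,
land-use mix and retail floor-area ratio; only the first two are
computable from generated data, so the surrogate score is the mean of the
z-scored meshblock dwelling density and z-scored intersection density
(per city). Meshblocks in the top/bottom tertile are classed high/low
and the middle tertile is excluded, maximising contrast as in the study
design. Study neighbourhoods are connected components (shared-boundary
adjacency) of ≥5 same-class meshblocks, up to `n_neigh_per_class` per
class per city (default 6, giving the 12-per-city design), ties broken by
unit id.

**Destinations.** A marked Poisson process per meshblock with intensity
by walkability class (defaults 14/7/4 per km² for high/excluded/low),
types 1–31 drawn uniformly and allocated to the eight domains as
education 4, transport 2, recreation 4, social/cultural 4, food retail 6,
financial 3, health 4, other retail 4 (sums to 31; fully overridable).

**Participants.** Residence is dwelling-weighted: a study neighbourhood
is drawn proportional to its occupied dwellings, then a member meshblock
by dwellings, then a uniform point within it. This emulates
household-based recruitment and places the cohort's local dwelling
density above the regional average, which is what makes median dwelling
density decline as buffers grow — a pattern that area-uniform placement
does not reproduce. Ages are uniform on [20, 65]; categorical covariates
(sex, ethnicity, income, marital status, education, employment, car
access, 5-level neighbourhood preference) follow fixed marginals.

**Outcomes.** For each of the five outcomes (transport walking,
recreation walking, total walking, mean counts/hour, % MVPA), the true
model is `log(y+1) = α_o + β·x + γ'z + u_city + u_nbhd + ε` with
independent Gaussian intercepts and residuals, `y = exp(·) − 1` truncated
at zero and % MVPA clipped at 100. Default variances are σ²_city = 0.02,
σ²_nbhd = 0.05, σ²_resid = 1.0 (null-model ICC ≈ 0.065, inside the 0.011–
0.136 range reported for such outcomes) and β = 0.05 per exposure unit.
Per-outcome intercepts are placed so medians resemble an adult suburban
cohort (~40 min/wk transport walking, ~8000 counts/h, ~12% MVPA). Total
walking is rebuilt as transport + recreation + non-negative noise so the
component ordering holds by construction rather than by rejection.

## Neighbourhood delineation

Motorways and ramps are removed before any buffer computation; the
operation is idempotent and leaves the input untouched. Homes snap to the
nearest edge polyline (ties to the lowest edge id; addresses farther than
`max_snap` = 500 m are excluded and counted, mirroring the study's
unlocatable-address exclusions).

Service areas use exact split-edge Dijkstra: the snapped origin seeds
both endpoints of its edge with the along-edge offsets, node distances
are truncated at the cutoff *d*, and each edge's covered sub-intervals
are derived analytically — covered `d − dist(endpoint)` metres from each
end, merged into full coverage when the two one-ended covers jointly span
the edge; the origin edge additionally carries the interval directly
reachable from the origin point. Tests verify the reached length against
brute-force Dijkstra on a 1-m-subdivided graph (integer grids make the
oracle exact; tolerance 0.5 m).

Polygonisation dilates the union of reached (sub)segments by half of
`width` (default 100 m, i.e. 50 m each side, round caps). Commercial GIS
"service area" polygons are dialect-specific; dilation was chosen because
it preserves nesting across cutoffs (B0500 ⊆ … ⊆ B1500 up to a 1e-6 m
tolerance), handles disconnected reaches, and has a closed-form area on
simple cases for testing. The half-width is a free parameter with no
canonical value; at the defaults, median B0500 areas land at 0.3–0.5 km²,
the right order of magnitude for 500-m pedestrian sheds.

Administrative assignment is inclusive point-in-polygon with boundary
ties resolved to the lowest meshblock id, giving platform-independent
determinism; the census area unit is the meshblock's parent and the study
neighbourhood comes from the meshblock's membership.

## Exposures

**Dwelling density** divides dwellings by residential hectares within the
polygon. For the three administrative definitions the count is the exact
member-meshblock sum (boundaries align); for buffers it is uniform-
density areal interpolation, Σ count × overlap/area over intersected
meshblocks, which conserves totals under any partition (tested to 1e-6).
Dasymetric refinement (restricting weights to residential land) is not
the default. A polygon with no residential land yields a missing value,
logged and excluded from modelling.

**Connectivity** counts nodes with ≥3 distinct incident edges (after
pedestrian filtering) inside or on the boundary of the polygon, divided
by area in km². Boundary-inclusive counting matches the inclusive
containment used everywhere else.

**NDAI.** Presence domains score one point per destination type with at
least one point in the polygon; the transport and recreation domains use
a per-type saturating density score `min(1, rate/ρ_ref)` with ρ_ref = 1
per km², so under unit domain weights the maximum is exactly 31. The real
index's density formulas are not public; this scoring keeps the shape
(density-based, bounded per type) without claiming numeric equivalence.
Consequence: the density terms fall with area at fixed counts, so strict
monotonicity of NDAI in neighbourhood size holds for the presence part
and for saturated density domains, while the default score is monotone in
the median but not guaranteed per participant.

## Accelerometry

30-s epochs, 2880 per day. Zero runs of ≥60 min (120 epochs) are
non-wear; the stated rule "greater than 59 minutes" is read as ≥60 min
and the 59-min boundary is tested explicitly. The ambiguous companion
clause ("worn for less than 60 minutes") is implemented as a minimum
wear-bout filter: wear bouts shorter than 60 consecutive minutes are also
excluded. Days need ≥10 h (1200 epochs) of wear; the minimum number of
valid days is configurable with default 1. Mean counts/hour is total
counts during wear on valid days over total wear hours; % MVPA is the
share of wear epochs at or above a count cutpoint. No cutpoint default is
shipped: published cutpoints are device- and epoch-specific, so the value
must be stated by the caller.

## Inference

Association models are fitted by REML with `statsmodels` MixedLM: random
intercept for city plus a variance component for neighbourhood within
city, fixed effects for the exposure and the full adjustment set
(preference entered as categorical). Outcomes are log(y+1); the offset
is recorded in every result. CIs are Wald at 95%; estimates and CIs are
reported as percentage change `100·(exp(·)−1)`, a strictly monotone map,
so the evidence flag (CI excluding zero) is identical on either scale.

Optimizer note: the profiled REML surface with a boundary variance
component defeats some optimizers; fits try BFGS, then Powell, then CG,
keeping the first converged result. Singular or failed fits fall back to
dropping the city component, then to OLS, each explicitly flagged — never
silently.

The LR test of clustering compares ML fits of the intercept-only model
with and without the two random intercepts and refers the statistic to a
50:50 mixture of χ²(1) and χ²(2), the boundary correction for two
variance components; under a clustering-free null this is conservative
(observed rejection ≈1–3% at nominal 5%). The adjusted ICC comes from the
intercept-only REML fit as (σ²_city+σ²_nbhd)/total. R² follows the
variance-partitioning definition for mixed models: R²m =
Var(Xβ̂)/(Var(Xβ̂)+σ²_city+σ²_nbhd+σ²_resid) and R²c adds the random
variances to the numerator.

Calibration experiments use group structures chosen so variance
components are estimable: type-I error and coverage replicate the study's
4 cities × 12 neighbourhoods at n = 2000 over 200 outcome replicates on a
fixed cohort (a parametric replication of the outcome model; geography is
not re-drawn); ICC recovery uses 50 cities × 5 neighbourhoods at
n = 5000, averaging 5 replicates, because a variance component estimated
from 4 clusters has sampling error far larger than the 0.02 tolerance of
interest.

## The sensitivity grid and the scale experiment

The grid fits all 3 × 5 × 7 = 105 models, flags evidence per cell, and
counts evidence cells per definition; the "consistency" count is this
package's operationalisation of a definition's propensity to detect
associations, with ties broken in the canonical order MB, UN, CA,
B0500–B1500. No multiple-testing correction is applied, matching
per-model 95% CI inference; the expected number of false-positive cells
under a global null (≈5% of cells) is printed alongside.

The scale-sensitivity experiment injects a true dwelling-density effect
at the B1000 exposure (β = 0.06 per dwelling/ha, n = 400, one seeded
geography, 20 outcome replicates) and compares detection across
definitions. β was calibrated at design time so that power at the true
scale is high but unsaturated: buffer-scale density is a neighbourhood-
level covariate, so its effective sample size is the number of
neighbourhoods (~20), not n, and naive per-observation power formulas
overshoot badly. With exposures sharing geography across scales,
correlation with the true-scale exposure is ~0.97–0.99 for adjacent
buffers but ~0.7 for the meshblock, so evidence concentrates at 800–1000
m and thins at the smallest definitions.

## Problem sizes and numerical choices

Tests run on a 4.48 × 4.48 km region (400 meshblocks, 4 cities, ~20 study
neighbourhoods) with cohorts of 120–400 for spatial stages and abstract
(geometry-free) cohorts of 1000–5000 for statistical calibration; these
sizes keep the full suite to a few minutes while leaving every estimate's
Monte-Carlo error well inside the asserted tolerances. Geometric
tolerances: 1e-6 m buffers for nesting checks, 0.5 m against the 1-m
subdivision oracle, 1e-6 relative for conservation. Buffer caps use
shapely's default circle approximation (~0.1% area error on a 50-m cap).
Deterministic tie-breaks throughout: lowest edge key for snapping, lowest
unit id for boundary point-in-polygon and tertile ties.

## Limitations

The generator's grid geometry, rectangular zoning and uniform covariate
marginals are deliberate simplifications: passing tests demonstrate the
correctness and calibration of the pipeline's computations, not that any
particular real city exhibits these effect sizes. Self-reported walking
outcomes are simulated from the same log-linear family as the objective
ones (no reporting error model). The walkability surrogate omits land-use
mix and retail floor-area ratio, and the NDAI density scoring is a
bounded stand-in for unpublished domain formulas. Pedestrian-only paths,
kernel-density exposure measures and spatial correlation structures
beyond the two-level random intercepts are out of scope.
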