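# Methods

`riversync` analyses how dams decouple the population dynamics of riverine
fish and how the resulting asynchrony among subpopulations stabilises
fragment-level metapopulations. This note documents the models, the
synthetic world the package is tested against, the numerical choices, and
the limits of what a green test establishes.

## River geometry

A river network is a rooted tree: edges are stored upstream → downstream
with positive lengths, and exactly one node (the outlet) has no downstream
edge. Braided inputs (a node with two downstream edges), cycles, multiple
components and multiple outlets are rejected rather than repaired, because
every downstream quantity assumes unique routes.

For two point placements on the tree (sites or dams are an `(edge, offset)`
pair, offset measured from the edge's upstream node):

- **Watercourse distance** `d_W` is the length of the unique connecting
  path, including partial edge offsets. It is a metric on tree points.
- **Flow-connectedness** holds iff one point lies on the other's downstream
  route to the outlet; a pair whose route descends through a confluence and
  climbs another tributary is flow-unconnected.
- **Barrier counting** intersects the route's per-edge intervals with the
  dam placements. A dam exactly coincident with one of the two sites is
  counted as *not* between (configurable via `count_barrier_at_site`);
  a dam placement is attached to its own edge, so a dam lying exactly on a
  shared node is credited to routes traversing that edge only. Both are
  measure-zero tie-breaks on continuous landscapes.
- **Fragments** are the connected components of the site graph whose edges
  join pairs with zero barriers on route; labels are deterministic (the
  smallest member site id). Euclidean distance `d_E` uses site coordinates;
  with straight (or polyline) edges `d_E ≤ d_W` always.

Real inputs (GeoJSON polylines, site/barrier tables in planar metres) are
snapped to the nearest network point by perpendicular projection with ties
broken by lowest edge id. Removed dams are dropped before any spatial work;
all remaining dams are treated as fish barriers because registry metadata
on passability is too patchy to model.

## Pairwise synchrony

Synchrony of a site pair is the Spearman rank correlation (average ranks
for ties) of their densities over jointly sampled years. A pair is excluded
when (i) fewer than `min_years` matching years exist (6 by default, 10 in
the sensitivity analysis), (ii) no matching year has positive density at
*both* sites — such all-zero co-occurrence biases correlations downward;
requiring "either" site positive is available but not default — or (iii) a
series is constant (undefined ranks). Exclusions carry reason codes.

Because between-fragment pairs can span longer distances than
within-fragment pairs, between-fragment records beyond the catchment's
maximum within-fragment `d_W` are removed ("truncation" implemented as
filtering, not distance capping — capping would fabricate distances; the
goal is equal ranges across groups). Fragment-level synchrony is the
arithmetic mean of within-fragment pair correlations.

## Multimembership mixed models

Each observation is a site *pair*, so residuals are not independent across
rows sharing a site. The model is

y = Xβ + Z_c u_c + Z_s u_s + ε,  u_c ~ N(0, σ²_c), u_s ~ N(0, σ²_s),

where `Z_c` is the catchment indicator and `Z_s` the multimembership site
incidence: each row carries weight 1 in both of its member sites' columns
(0.5 optional). Fixed effects combine √(d_W in km), flow-connectedness and
barrier crossing with their interactions; the square-root transform
linearises the empirical distance decay.

Estimation is profiled REML (ML for model comparison): the residual
variance is profiled out analytically and the two variance *ratios* are
optimised by L-BFGS-B bounded at zero (Powell fallback), tolerance 1e-8,
starting from an equal split of the OLS residual variance. Likelihood
evaluations use the Woodbury identity so each step costs O(q³) in the
number of random levels, not O(n³). The fit is cross-validated in the test
suite against R's lme4 (coefficients, SEs, variance components and REML
log-likelihood agree to ≈6 significant digits) and against a dense-matrix
grid-search oracle. A component estimated on the zero boundary is flagged
singular; a random effect with a single level is pinned to zero (it is
confounded with the intercept and its REML ridge is flat) and flagged.

Wald t statistics use the large-sample normal reference — the pairwise
datasets have hundreds to thousands of rows, where the difference from a
t/Satterthwaite reference is negligible; the type-I simulation below checks
this choice. R² follows the variance-partitioning convention:
marginal = var(Xβ̂)/(var(Xβ̂)+σ²_c+σ²_s+σ²_e); conditional adds the random
components to the numerator. AIC = −2 logLik + 2k (k = fixed + variance
parameters) and is compared across fixed-effect specifications only for ML
fits. Note: REML coefficient estimates are *not* invariant to duplicating
every observation — duplication changes the estimated variance ratios and
hence the GLS solution; only the OLS limit has that invariance.

**Type-I calibration.** Null panels (identity correlation, no trends) keep
the riverscape covariates but make every fixed effect truly zero. Fitting
the full three-way model to ≥500 such panels, the per-term rejection rate
at α = 0.05 is within 3 binomial SEs of 5% for every non-intercept term.

## Portfolio effect

Taylor's power law, variance = c·meanᶻ, is fitted by OLS on log10–log10
axes across all subpopulation (site) series of a species, pooled over
fragments. When z is within 0.1 of 2 the average-CV portfolio effect is
permissible; otherwise the more conservative mean-variance-CV metric is
required. For an eligible fragment (≥4 subpopulations with ≥10 sampled
occasions each) the metapopulation series is the per-year sum over the
years *all* eligible subpopulations were sampled (strict common-year rule —
a deliberate, conservative choice; coverage-based imputation was considered
and rejected as fabricating data). Then

PE = CV_uniform / CV_observed,  CV_uniform = √(10^log₁₀c · μ_T^z) / μ_T,

with μ_T the metapopulation mean. PE is oriented so that PE = 1.5 reads "1.5
times more stable than one uniform population of the same size": two
independent equal-CV subpopulations under z = 2 give PE → √2, perfectly
correlated identical subpopulations give PE → 1, and PE is non-increasing
in within-fragment correlation. PE is scale-free exactly when z = 2;
otherwise multiplying all densities by a constant moves CV_uniform — a
documented property of the metric, not of this implementation. The
association of PE with fragment mean synchrony is a mixed model with a
catchment random intercept.

## Performance metrics

Per site: occurrence rate (fraction of sampled occasions with positive
density), mean and SD of log(density+1) — the SD is computed on the log
scale for consistency with the mean (a raw-scale SD is available) — then
averaged (unweighted) within fragments. Per fragment: one regression of
log(density+1) on year in interaction with site identity, i.e. fully
separate per-site intercepts and slopes (equivalent fits, identical
residuals; sites need ≥3 occasions). The pooled residual SD is the
detrended variability — adding a common linear trend to every site changes
the trajectory, never the residual SD — and the trajectory is the equal-
weight mean of per-site slopes. Each of the five metrics plus the portfolio
effect is regressed on fragment mean synchrony (catchment random
intercept); the six p-values per species form one Benjamini–Hochberg
family.

## Synchrogram categories and the barrier test

For each pair, `q = d_E/d_W ∈ (0,1]` indexes functional connectivity.
Catchment-wise median splits of `d_E` (short/long) and `q` (high/low) give
D1 (short, high: same branch, near), D2 (long, high: same branch, far),
D3 (short, low: nearby separate branches), D4 (long, low: distant separate
branches). Ties at the median go to the lower class (short/low), with one
exception: q = 1 exactly (Euclidean equals watercourse distance) is always
"high", since a straight single-channel river must yield only D1/D2 —
the tie rule and that degenerate case cannot both be honoured otherwise.
Pairs with d_W = 0 are excluded. Category assignment is invariant to
rescaling distance units.

Two ML fits with the same random structure as the synchrony models —
synchrony ~ category, and synchrony ~ category + category×barrier (one
barrier column per category observed in both barrier classes; empty cells
dropped and logged) — are compared by AIC and a likelihood-ratio test. ML,
not REML, because the fixed effects differ. Under a true barrier effect the
barrier model wins and the largest within/between-fragment gap sits in D1,
where baseline synchrony is highest.

## The synthetic world

The generator *is* the stated study system, not a tuning knob:

- 6 catchments, each a random bifurcating tree of 30 reaches (lengths
  uniform 0.5–5 km), 60 electrofishing sites and 5 dams per catchment
  (dams on distinct reaches; about 4–6 fragments per catchment, matching
  the fragment density of Swedish survey catchments), 30 survey years,
  each site sampled each year with probability 0.5 (≈15 occasions per
  site; retained pairs average ≈7–8 matching years).
- Pair correlation target C_ij = s0·exp(−d_W/ρ)·β^[barrier]·γ^[unconnected]
  with defaults s0 = 0.5 (an observed within-fragment Spearman near 0.4 at
  short distance, matching electrofishing studies), ρ = 10 km, β = 0.4,
  γ = 0.5. Archetypes: "trout-like" (those defaults — strong decay, strong
  barrier decoupling) and "pike-like" (ρ → ∞, β = γ = 1 — catchment-wide
  synchrony, no barrier response). The multiplicative form need not be
  positive semidefinite, so the matrix is projected to the nearest PSD
  matrix by eigenvalue clipping at 1e-8 (maximum adjustment logged).
- Observation model: site log-density = intercept (N(2, 0.7²)) + site trend
  (slope N(0, 0.01²) per year) + correlated deviate × 0.6; density is its
  exponential, set to zero with hurdle probability 0.1 (electrofishing zero
  catches), and each site-year retained with the sampling probability.
- Null panels for calibration use the same riverscape with identity
  correlation and zero trend SD.

What the generator does *not* emulate: demographic processes (no stage
structure or explicit dispersal kernels), observation error in density,
temporal autocorrelation, Taylor-law-consistent mean–variance scaling
across sites, or non-stationary sampling design. A green test therefore
establishes that the estimators recover the stated correlation geometry
from zero-inflated, irregularly sampled panels — not that they would
recover parameters from demographically realistic dynamics.

## Numerical choices and degenerate inputs

- Spearman uses average ranks; constant series are excluded, never assigned 0.
- Catchments with no within-fragment pair lose all between-fragment pairs at
  truncation (warning).
- Fragments with fewer than the eligibility thresholds are reported with a
  reason, not silently dropped; empty common-year sets drop the fragment.
- Rank-deficient fixed designs raise an error naming the collinear columns.
- Variance components are bounded at zero; boundary fits are flagged (†-style)
  rather than suppressed.
- All randomness flows from one seed through `numpy.random.SeedSequence`
  spawning; pipeline outputs are byte-identical across reruns.

## Known limitations

- Power at the default synthetic scale is borderline for detecting β = 0.4
  via the barrier main effect at p < 0.05 (measured ≈88% of replicates);
  sign recovery is near-certain.
- The normal-reference p-values are slightly anti-conservative in principle
  for small fragment-level regressions (n ≈ 20–100 fragments); the
  simulation checks cover the pairwise models, not every fragment-level fit.
- Real-mode ingestion assumes planar metre coordinates and one network
  component per catchment; no reprojection or braided-channel resolution.
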