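# Methods

## The model

The analysis unit is the *ordered pair* of adjacent areal units. For index
unit *j* with neighbor *i*, the response is the outcome difference
ΔY<sub>ij</sub> = Y<sub>j</sub> − Y<sub>i</sub> and the design holds covariate
differences (ΔX<sub>k</sub>)<sub>ij</sub> plus a 0/1 modifier flag marking one
direction of each unordered pair. Rows are nested in their index unit, giving
the two-level structure:

ΔY<sub>ij</sub> = (β₀ + b₀<sub>j</sub>) + Σ<sub>k</sub> (β<sub>k</sub> + b<sub>kj</sub>)(ΔX<sub>k</sub>)<sub>ij</sub> + γ·modifier + f_spat(j) + ε,  ε ~ N(0, σ²<sub>resid</sub>)

* **Fixed effects** β (intercept, covariate coefficients, modifier
  coefficient γ) carry zero-mean normal priors with variance 10⁶
  (configurable). A proper but very diffuse prior keeps every full
  conditional proper; at this scale it is numerically indistinguishable from
  a flat prior for data on per-100,000-rate scales.
* **Random intercepts and slopes** are independent zero-mean normals per
  unit, one variance per family; no intercept–slope covariance is modelled.
* **Spatial term** f_spat follows the intrinsic conditional-autoregressive
  (CAR) prior: conditionally, f_spat(s) | rest ~ N(Σ<sub>s′∈ω(s)</sub>
  f_spat(s′)/N<sub>s</sub>, σ²<sub>spat</sub>/N<sub>s</sub>), where ω(s) are
  s's queen-contiguity neighbors and N<sub>s</sub> = |ω(s)|. The joint kernel
  is the improper pairwise-difference form
  exp(−Σ<sub>edges</sub>(f<sub>s</sub> − f<sub>s′</sub>)²/2σ²<sub>spat</sub>).
* **Variance components** (random intercept, each slope family, spatial,
  residual) carry inverse-gamma(a, b) priors with a = b = 0.001 by default.
* **Identifiability.** Every random-effect family is constrained to sum to
  zero. We re-center (subtract the mean) after each family's update rather
  than sample under the constraint — the standard intrinsic-CAR fix, cheaper
  and equivalent in distribution for Gaussian models.
* **An explicit residual term.** The difference equation needs a noise term
  for a Gaussian likelihood to exist; ε gets its own IG(a, b)-priored
  variance, and a known-variance reduction (`fixed_resid_variance`) is
  provided for conjugate checks.
* **Binding of f_spat.** The spatial effect is indexed by the *index* unit j
  of each row, consistent with the level-2 nesting; this is a modelling
  choice, as the alternative (the neighbor unit) is equally expressible.

Note an asymmetry worth being explicit about: the data construction is
antisymmetric (reversing a pair negates every Δ), but the model's intercept,
random effects, and spatial term attach to the index unit only, so the model
itself is not antisymmetric. The modifier flag exists to absorb this
duplication; on balanced all-ordered-pair data its coefficient is essentially
unidentified noise around zero, and removing it leaves the covariate
estimates unchanged up to Monte-Carlo error (this is verified by test).

## Gibbs sampler

All full conditionals are conjugate. One sweep updates, in a fixed default
order: the fixed-effect block (multivariate normal), each random-intercept
site, each random-slope family, the spatial field, then every variance
(inverse-gamma with shape a + m/2 and rate b + SS/2, where m counts the
effects and SS is their sum of squares; for the intrinsic CAR m is the rank
of the CAR precision, N − number of connected components, and SS the edge sum
of squared differences). The spatial field is updated by a **chromatic
scan**: a greedy graph coloring partitions units into classes with no
internal edges, each class is drawn jointly (its members are conditionally
independent), and classes are visited sequentially — the same stationary
distribution as a site-by-site scan, but vectorizable. Validity of every
conditional is tested by grid-normalizing the joint density in single
coordinates (1e-6 pointwise relative tolerance) and, for the whole sampler,
by matching the closed-form posterior of a known-variance conjugate
reduction.

The default schedule is 25,000 iterations, 5,000 burn-in, thinning 20
(1,000 stored draws). Numerical failure modes are surfaced, not patched: a
singular fixed-effect precision or a non-finite state aborts with the
component or iteration named.

## Summaries

Credible intervals are empirical equal-tail quantiles of stored draws with
linear interpolation between order statistics (a convention; recorded because
quantile rules differ across software). DIC uses the Spiegelhalter plug-in at
the posterior mean of *all* parameters, variance components included:
pd = dbar − D(θ̄), DIC = dbar + pd. Model selection fits each candidate with
an independent chain seeded `base + index` and breaks DIC ties toward fewer
covariates. Trace-plot inspection is replaced by assertable diagnostics — a
Geweke-style z (first 10% vs last 50% of stored draws, flag |z| > 2) and
lag-1 autocorrelation — with trace plots still emitted for human review.
Constant series are reported degenerate, never flagged divergent.

## Descriptive conventions

Antisymmetry forces the mean of any Δ over *all ordered pairs* to be exactly
zero, so a non-zero "average mean difference" must come from another
convention. Three are implemented and labelled: `all-ordered-pairs` (a
consistency check), `two-stage` (mean within each index unit, then across
units — the default), and `modifier-1-only` (one direction per pair). Sample
SD (ddof = 1) is the default; the extreme-pair flags (≥ 1 SD, ≥ 2 SD of the
outcome difference) use the population SD over all ordered pairs, both
configurable.

## Synthetic data

Two generators, deliberately distinct:

* **County-level** (`simulate_county_table`): covariates are neighbor-
  averaged noise fields rescaled so the realized between-neighbor difference
  SD matches its target exactly on the generated graph; the outcome adds the
  linear combination at the true coefficients, a smooth spatial field, and
  white noise with per-unit SD resid_sd/√2 (so pair differences of the noise
  have SD ≈ resid_sd). This path exercises differencing, antisymmetry
  invariants, and descriptives.
* **Model-faithful** (`simulate_pair_outcomes`): ΔX columns are drawn i.i.d.
  per ordered row and ΔY comes from the model equation at known truth. This
  is the generator for sampler-correctness and coverage experiments —
  because the model is not antisymmetric, rows here are *not* negated pairs,
  and using the county-level path for recovery tests would confound model
  error with construction error.

Default conditions: 115 units; random planar graphs (Delaunay triangulation
pruned to mean degree ≈ 5.1, maximum 8, one peripheral unit pared to a single
neighbor, mirroring a U.S. state county map); true coefficients
(2.60, 1.03, 2.93, 4.75, 6.08) and covariate difference SDs
(3.68, 25.55, 4.91, 3.99, 4.15) on the scales a county mortality-difference
analysis reports; random-intercept SD 10, slope SD 0.3, spatial SD 15,
residual SD 80 (≈ half the outcome-difference variance structured). The
"strong-effect regime" used for DIC-ordering and sensitivity experiments
keeps the same truth with residual SD 40. A synthetic boundary map (clipped
Voronoi tessellation of random points, labelled synthetic) exercises the
polygon → queen-contiguity path at state-map scale.

What the generators do *not* emulate: survey sampling error in covariates,
realistic geographic shapes, cross-border adjacency beyond the supplied map,
and spatial confounding between covariates and the spatial field (ΔX in the
model-faithful path is independent of f_spat). Passing tests therefore
demonstrate correctness of the algorithmic machinery and calibration under
the model's own assumptions, not robustness to misspecification on real
surveillance data.

## Problem sizes and experiment design

Recovery experiments use 50 replicates at full spatial size (115 units,
~580 ordered rows) with a shortened schedule (5,000/1,000/10 → 400 stored
draws), which keeps per-parameter Monte-Carlo error well below posterior
spread; DIC and hyperprior-sensitivity experiments use 20 replicates and
4 grid fits at 2,000/500/5. Coverage is judged by a two-sided binomial test
against 0.95 at α = 0.01.

## Known limitations

* Single-chain design: no between-chain R-hat; diagnostics are within-chain.
* The intrinsic CAR is improper; inference relies on the sum-to-zero
  constraint, and disconnected maps are handled by rank correction only.
* Random slopes are independent across covariates and units; no covariance
  structure is available.
* Shapefile input is not supported; boundary data enter as GeoJSON or as a
  precomputed edge list.
* With IG(a, b) priors at very small a, b and weak data, variance components
  can mix slowly near zero; the sensitivity scan exists precisely to check
  that fixed-effect conclusions do not depend on this choice.
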