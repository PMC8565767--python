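# Methods

## Model

The response is the binary presence of fire in a ~1-km pixel in a given
year. With nine covariates `x_1..x_9` (two climate normals, two three-year
climate deviations, focal housing density, cultivated fraction, two
infrastructure distances, years since fire), the model is a binomial
additive model on the logit scale:

    logit P(burn) = b0 + sum_j f_j(x_j)

Assumptions worth stating explicitly:

- **Conditional independence.** Given the covariates, pixel-years are
  treated as independent Bernoulli trials. Fire spread, event contiguity
  and within-year multiplicity are not modeled; the object of inference is
  probability, not fire behavior.
- **Additivity.** No interaction or tensor smooths; each covariate
  contributes a univariate curve. Regional refits are the only mechanism by
  which relationships may vary over space.
- **Left-censored fire record.** A pixel with no recorded prior burn is
  assigned the cap value (default 100 years); truly unburnable terrain and
  merely unobserved history are indistinguishable at this point, which
  drags the upper end of the years-since-fire curve toward the average of
  both populations.

## Smooths and fitting

- **Basis.** Natural cubic regression splines parameterized by their values
  at `k` knots (default `k = 5`), knots at evenly spaced quantiles of the
  *unique* covariate values, always including the min and max. Quantiles of
  unique values — rather than of the raw data — keep a heavy atom (nearly
  half the mass of years-since-fire sits exactly at the cap) from
  collapsing knots, and keep knots out of gaps in the support, where a
  data-free knot coefficient is unidentified. The natural-spline
  second-derivative map gives exact evaluation between knots and the exact
  curvature penalty `∫ f''²`; the penalty null space is constants plus
  linears.
- **Identifiability.** Each smooth carries a sum-to-zero constraint over
  the training rows, absorbed by an orthonormal reparameterization (`k-1`
  free coefficients per term, matching a reference df of 4 at `k = 5`).
  The bound of five coefficients per covariate is deliberate: enough for
  hump-shaped and saturating responses, small enough to keep fits cheap
  and stable at scale.
- **Optimization.** Penalized IRLS with step halving, so the penalized
  deviance is monotonically non-increasing; convergence when the relative
  change falls below 1e-8, cap of 200 iterations. Diverging coefficients
  (perfect separation) trigger a warning and a small-ridge refit.
- **Smoothing parameter.** GCV `n·D/(n-τ)²` on a log-spaced grid
  (`1e-2 … 1e6`, 13 points) with one λ shared across terms by default;
  per-term coordinate refinement and fixed λ are available. With the small
  bases used here and tens of thousands of rows, the GCV profile is nearly
  flat and typically selects light smoothing — the basis dimension, not λ,
  is the binding complexity control, which is the intended design.
- **Degenerate covariates.** A covariate with fewer distinct values than
  the basis dimension (common inside small regions — e.g. a quadrant with
  no cultivation) degrades gracefully: shrink the basis, fall back to a
  single linear column below three distinct values, drop a constant column
  entirely. Each degradation warns.
- **Prediction outside the training range** clamps the covariate to the
  range rather than extrapolating the cubic — conservative, and the right
  behavior for cross-validation folds that must predict in novel regions.
- **Training modes.** A single pooled fit is the default; a
  leave-one-year-out mode (one model per year of interest, trained on all
  other years) is provided for strict out-of-year prediction.
- **Term tests.** Per-term Wald chi-squared statistics with EDF-based
  reference df are reported as *approximate*; penalized estimation makes
  the reference distribution approximate by nature, and no attempt is made
  to reproduce any particular reference implementation's test.

## Sampling

Poisson-disk thinning over the finite candidate lattice: visit candidates
in seeded random order, accept iff no accepted pixel lies within the
minimum distance (default 5 km between cell centers). The result is maximal
under the visiting order; a uniform spatial hash with bucket width equal to
the distance makes each check O(1). Blue-noise spectral quality is
irrelevant here — only the hard distance guarantee and maximality matter.

## Cross-validation

Years and sampled pixels are each partitioned into `n_groups = 10` random
near-equal groups. Iteration `i` pairs temporal group `i` with spatial
group `i` (ten iterations; the full 100-pair grid is available via
`full_grid=True`). AUC is pooled over all pixel-years in a test cell, not
averaged per year. Test cells (or training folds) with a single class
record a missing AUC with a warning and are dropped from means, with counts
reported. Regional CV shares the temporal partition with the statewide plan
(matching folds for paired comparison) and reassigns spatial groups within
each region with a seed derived from the plan seed and region id; a region
holding every pixel of the plan reuses the plan's spatial groups verbatim,
so a one-region landscape reproduces the statewide CV exactly.

## Counterfactual decomposition

Null values: training mean for the climate normals (no meaningful zero),
zero for housing density, cultivated fraction and the climate deviations,
training maximum for the distances (zero distance is where influence
peaks). Years since fire has no established null; it is pinned to the
training mean, an extension flagged in the report output. Correlations are
computed over the pixels present in the supplied record table (the sampled
pixels by default; pass a table over all valid pixels for full maps), and
the observed-frequency side may use a longer record than the prediction
period when prior-burn years are available.

One behavior of the decomposition worth knowing: on simulated data the
time-since-fire-only sub-model can correlate *negatively* with observed
burn frequency. That is real, not a bug — frequently burning pixels spend
more years inside the post-fire refractory window, so a sub-model seeing
only years-since-fire assigns them lower probability.

## Synthetic landscapes

The generator draws spatially autocorrelated Gaussian surfaces (white noise
smoothed at the correlation range, default 10 km, restandardized) for
climate normals; annual layers add independent per-year anomaly fields
(sd 50 mm). Housing is a smooth background plus a few Gaussian urban cores
growing 15% per decade, snapshotted decadally and linearly interpolated in
time. Roads and transmission lines are straight rasterized transects;
cultivated and water fractions are clipped smooth fields; regions are a
rectangular tiling. The fire process applies the configured effect
functions to the *same* covariates the model later sees (including the
dynamic years-since-fire state), passes the sum through an inverse logit,
and draws independent Bernoulli burns; a 100-year burn-in settles the
years-since-fire distribution and the last 30 burn-in years are recorded,
emulating a perimeter archive that predates the modeling window.

Default generating effects: a hump in AET normal (productivity), a
rise-then-fall in CWD normal (dryness helps until fuel runs out), mild
positive slopes in both deviations, a hump in housing density peaking at
intermediate development, strong suppression by cultivation, exponential
decay with both infrastructure distances, and a saturating years-since-fire
ramp rising rapidly over the first ~20 post-fire years. The default
intercept (−10.6 log-odds) was calibrated once so these effects yield a
marginal burn rate of roughly 1–2% of pixel-years, matching a realistic
annual fire incidence; the rate is configurable through `true_intercept`.

What the generator does **not** emulate — and therefore what passing tests
cannot certify about real data: fire spread and event-shaped burn clusters,
vegetation-type dynamics, observation error in perimeter mapping,
non-additive covariate interactions, and covariate measurement error. Tests
against this generator certify that the pipeline recovers an additive truth
of realistic shape and rarity, not that real fire is additive.

## Problem sizes

The test suite exercises most properties on a 32×32-km, 25-year landscape
(~25k pixel-years; ~230 training pixels after 2-km thinning), chosen so the
full suite stays fast while every stage still sees two-digit burn counts.
Ground-truth shape recovery is asserted on a 64×64-km, 40-year landscape
(>100k training rows), where every fitted curve correlates with its
generating function at r ≥ 0.9 over the data-quantile grid — curves are
compared where data identify them. Heavier CV tests use a fixed λ = 1
because fold integrity and skill ordering, the properties under test, do
not depend on the smoothing-parameter search. The acceptance script runs
the 64×64, 40-year configuration with 2-km thinning and full GCV.

## Known limitations

- The statewide-versus-regional comparison is made under a spatially
  homogeneous generating truth; with strongly regionalized truths the
  ordering could differ.
- GCV with a shared λ across terms can under-smooth weakly informative
  terms; per-term refinement is available but quadratic in the number of
  terms.
- The 100-year years-since-fire cap conflates old-burn and never-observed
  pixels (inherited from the data situation the pipeline mirrors).
- Distances are center-to-center Euclidean on the grid; no geodesic or
  network distances.
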