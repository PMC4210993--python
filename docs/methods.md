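# Methods

This note documents the model, the numerical choices, and the synthetic
study design behind `stokbg`, and what the shipped tests do and do not show.

## Model

The total concentration at a space/time point p = (s, t) is treated as the
sum of a local-source contribution and a regional background,
Z(p) = Z_LS(p) + B(p).  Dispersion is approximately additive, which makes
the decomposition meaningful; strongly non-linear chemistry is outside the
model (see Limitations).  `stokbg` estimates B; Z_LS comes from an external
dispersion model and is simply added at the end.

B(p) is decomposed as a constant offset o_B plus a homogeneous/stationary
Gaussian space/time random field X(p).  All estimation happens on the
transformed data x(p) = b(p) − o_B; the offset is added back afterwards.

### Data model

* **Hard data** — hourly observations at monitors whose regulatory objective
  is *general background* and that lie at least `min_distance_km` (default
  60 km) from the local-source region.  At such distances the local plume
  has decayed to a negligible fraction, so the observed total is taken as an
  exact measurement of B.
* **Soft data** — observations z at every other monitor, scaled by the
  random ratio R = zero-out/total of two chemistry-model runs.  R at a
  station's grid cell is summarized by the temporal mean μ_R and the
  unbiased (n−1) variance σ²_R of the hourly ratios after removing values
  below the 1st or above the 99th percentile (linear-interpolation
  percentiles).  A soft datum has mean z·μ_R and known error variance
  z²·σ²_R.  The ratio moments are per-station constants: they are paired to
  observations by station cell, never by timestamp, so model-run years need
  not match observation years.

The offset o_B is the mean of all *exact* data — hard values plus any soft
datum whose error variance is exactly zero (which happens precisely when
the two model runs coincide and σ²_R = 0, or z = 0).  Values are summed in
sorted order so the offset is independent of assembly order.  This
definition makes the degenerate case "zero-out ≡ total" collapse the
soft-data pipeline *bitwise* onto the all-hard pipeline.

### Covariance

X carries a nested sum of separable exponential structures

    C(r, τ) = Σ_i c_i exp(−3 r / a_ri) exp(−3 τ / a_ti),

with sills c_i (concentration²), spatial ranges a_ri (km) and temporal
ranges a_ti (hours).  The factor 3 makes each range the ≈95% decorrelation
scale — the common geostatistical "practical range" convention; packages
differing in this convention differ by that factor in the reported ranges.
Three structures are the default (`n_structures` configurable): a
synoptic/long-range component, a mesoscale component, and a short local
component.

**Empirical estimation.**  Data are grouped by exact location; for each
integer temporal lag, cross products between all location pairs reduce to
matrix products over the common hour axis, so the estimator runs in seconds
on ~10⁵ data.  Pairs are binned by spatial distance (default edges: a
degenerate [0, 1 nm) bin for collocated pairs, then every 25 km to 400 km)
and temporal lag (0, 1, 2, 3, 6, 12, 24, 48, 72 h).  The zero-distance bin
matters: same-site pairs give a clean C(0, τ) profile that pins the sill at
the origin.  Without it the first bin's representative lag sits near 9 km
on a dense network and the fitted total sill is essentially unconstrained
(we observed ~1.9× inflation).  Each bin records its pair-count-weighted
mean spatial and temporal lag, and the fit evaluates the model at those
mean lags rather than at geometric bin centers — the standard cure for the
within-bin lag distribution being skewed.

**Fitting.**  Pair-count-weighted least squares over the nonmissing bins,
parameters in log space, `scipy.optimize.least_squares` (trf) with
multi-start (default 20 starts, deterministic given the seed).  Fits are
grown recursively: the best k-structure fit, extended by a negligible extra
structure, seeds the (k+1)-structure fit, so adding structures can never
raise the weighted SSE.  Structures are reported sorted by descending sill.
Bins are canonically ordered before fitting, making the result invariant to
bin permutation.

**Which data feed the fit.**  The pipeline default fits the covariance on
the hard subset only (`PipelineParams.fit_on="hard"`).  Soft means carry
measurement error comparable to the field variance; feeding them into a
plain pair-product estimator inflates the fitted sill (≈2× on the default
synthetic study) and destroys the calibration of the kriging variances
(standardized LOO residual variance ≈ 0.3 instead of ≈ 1).  `fit_on="all"`
is available, and the `empirical_covariance` operation itself accepts any
dataset (soft data enter through their means; their variances are ignored
at that stage).

### Kriging

Ordinary kriging with measurement error: weights solve

    [C + diag(v)   1] [λ]   [c₀]
    [1ᵀ            0] [μ] = [1 ]

where v_i is datum i's error variance (0 for hard).  Estimate Σλᵢxᵢ,
variance C(0,0) − λᵀc₀ − μ.  Consequences used as tests: exact
interpolation (zero variance) at hard data; a single isolated hard datum
gives variance 2(C(0,0) − c); a single collocated soft datum returns its
mean and variance v; as v → ∞ a soft datum's weight → 0.

Estimation is local: candidates within `space_radius` (500 km) and
`time_radius` (72 h) are ranked by the combined distance r + ρ·τ with
ρ = a_r1/a_t1 of the dominant fitted structure (km per hour), and the
nearest `max_hard` (30) hard and `max_soft` (30) soft data are kept, ties
broken by (distance, datum id).  Local neighborhoods keep an hourly,
multi-receptor problem tractable; with the default radii the neighborhood
always includes the same-site, same-hour datum when one exists, preserving
exactness.

Numerical guards: collocated duplicates are resolved before the solve (hard
beats soft; conflicting hard values are an error; collocated soft data merge
by precision weighting — a zero-variance soft datum counts as hard); if the
factorization fails, a ridge of 1e−10·C(0,0) is added once and the solve
retried; kriging variances in (−1e−9, 0) are clipped to zero, anything more
negative is an error.  Back-transformed negatives are floored at 0 by
default, flagged, with the raw value preserved; points whose hour lies
outside the data's time span are flagged `extrapolated`; points with an
empty search window are returned flagged `unestimable`, never dropped.

### Hybrid combination and evaluation

Totals are background + local, joined on (receptor, hour); unmatched keys
are reported, duplicates are errors, and additivity is exact by
construction.  Evaluation pairs predictions with observations strictly by
(site, hour); metrics are bias, RMSE, ratio of means and the
boundary-inclusive fraction within a factor of 2, per site and pooled.
Monthly aggregation averages the paired hours of each calendar month and
flags site-months with < 75% paired-hour coverage.

Cross-validation withholds a site's *entire* series (withholding single
hours would leak through the same site's adjacent hours) and re-estimates
each withheld hour from the remaining data.  Standardized residuals
(residual / kriging standard deviation) should have mean ≈ 0 and variance
≈ 1 when the covariance model and the error model are right; this is the
package's calibration check.

## Synthetic study design

The generator emulates exactly the statistical structure the estimator
assumes, with one seed driving four independent streams (field, observation
noise, zero-out noise, total noise):

* **Background**: Gaussian field with the nested separable covariance and a
  constant mean, floored at 0.  Sampling is exact: the hourly exponential
  temporal factor is an AR(1) process (ρ = e^(−3/a_t)), so each structure
  is drawn as (spatial Cholesky factor) × (AR(1) innovations) jointly at
  *all* grid-cell centers, monitors and receptors — gridded fields and
  point observations are one consistent realization.  Default: sills
  (0.55, 0.35, 0.10), spatial ranges (300, 90, 25) km, temporal ranges
  (36, 12, 3) h, mean 7.8 — magnitudes chosen to resemble an urban PM2.5
  background (≈7–8 µg/m³ with ≈1 µg/m³ standard deviation).  The floor
  fraction is reported and stays ≪ 1% under the defaults, so the Gaussian
  moment checks remain valid.
* **Local sources**: L(s, t) = Σ strength · exp(−d/decay) · (1 + A·sin(2πh/24)),
  three point sources inside a 4×4 block of 12-km zero-out cells in the
  middle of a 30×30-cell grid; strengths 4–8 units, decay lengths 6–10 km,
  diurnal amplitudes 0.3–0.5.  The same closed form supplies the
  "dispersion model" receptor concentrations, so the local input is exact.
* **Monitors**: 10 background sites on an 85–125 km ring around the block
  (validated ≥ 60 km by construction) and 10 nonbackground sites, six of
  them inside the block; observations are Z plus N(0, 0.1²) noise, floored.
  The small observation noise mirrors the method's own assumption that
  monitor error is negligible against ambient variability.
* **Model runs**: "zero-out" = cell-aggregated B and "total" = cell
  aggregated Z, each multiplied by independent lognormal noise
  (σ = 0.05) — a stylized 5% cell-hour model error that generates the
  spread in the hourly ratio series.

Default problem sizes — 720 hours for the study scenario, 100 background
sites × 4000 hours for the covariance-recovery experiment, 240 sampled
hours per site in cross-validation — were chosen so the full pipeline runs
in minutes while leaving enough effective samples for the moment and
calibration checks.

What passing tests on this generator do **not** show about real data: the
real background is not Gaussian nor exactly stationary; real ratio series
have temporally correlated (diurnal, synoptic) errors rather than
independent lognormal noise, so real soft variances are optimistic at some
hours; real dispersion-model output carries errors the closed-form local
field does not; and monitor siting is not a neat ring.

## Design choices on genuinely open points

* **Trimming interpretation**: "below 1% / above 99%" is implemented as
  percentile-*value* trimming with linear interpolation, the most common
  convention.  Note this operation is not idempotent in general — repeated
  trimming recomputes interpolated bounds on the survivors and can keep
  shaving extremes — so it is applied exactly once.
* **Ratios > 1** are retained before trimming (the ratio's support is only
  nominally [0, 1]; model noise produces values slightly above 1, and
  trimming is the only guard).  Bounded-support (e.g., Beta) soft-data
  models would need a non-linear estimator and are out of scope.
* **Projection**: a local equirectangular projection converts lon/lat to
  planar km at ingest (sub-cell accuracy for domains a few hundred km
  across); all geometry downstream is planar.
* **Grid cells** are half-open and 0-based; a station on a cell's right/top
  edge belongs to the next cell, making station→cell pairing unambiguous.
* **Time** is an integer hour index against a configured epoch; timestamps
  are floored to the hour at ingest.  A ±1-year window around the analysis
  year can be applied at ingest (on by default in the CLI when the year is
  configured).
* **Old-hybrid variant** exists solely for the comparison experiment: the
  identical pipeline with every monitor's observations entering as hard
  data and the covariance fitted to that all-hard dataset.

## Known limitations

* The 3-structure nested exponential model is only weakly identifiable from
  binned covariances: neighbouring structures trade sill mass, so while the
  *total* sill is recovered to a few percent on the default network, the
  per-structure range attribution scatters by ~20–35% across realizations.
  Quantities that depend on the whole covariance function (estimates,
  variances, calibration) are insensitive to this trade-off.
* Additivity Z = Z_LS + B linearizes chemistry; the Gaussian soft-data model
  puts mass outside the ratio's [0, 1] support.  Both are inherited modeling
  assumptions, not implementation choices.
* Soft-data error variances are treated as known and independent across
  hours; temporally correlated ratio errors are not modeled.
* No anisotropy, no nugget-only models, no cokriging across pollutants.
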