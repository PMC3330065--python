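# Methods

## Problem and scope

`ozonemap` maps ground-level ozone exposure over a region from a sparse
rural monitoring network. Two station-level metrics are derived from
hourly concentrations for the vegetation season (April–September):

* the **seasonal mean** concentration (ppb), and
* **AOT40F** (ppb.h), the accumulated excess over 40 ppb during daylight
  hours — the phytotoxic exposure index used for forests.

Eleven interpolation methods turn the station metrics into continuous
surfaces, and leave-one-out cross-validation (LOOCV) RMSE decides which
method to trust. The package also ships a synthetic-data generator that
reproduces the statistical structure such a study assumes, so the whole
chain is testable without access to any monitoring archive.

## Exposure metrics

Hourly values carry validity flags; **data capture** is the fraction of
calendar-possible hours in a window that are valid (absent hours count
as missing). The seasonal mean requires capture ≥ 0.75, below which the
station is flagged absent — never zero-filled. AOT40 accumulates the
strict excess max(c − 40 ppb, 0); hours exactly at 40 ppb contribute
nothing.

Choices the literature leaves open, fixed here and configurable:

* **Daylight window** for AOT40: fixed clock hours 08:00–20:00 (twelve
  hourly values per day), one fixed timezone, no DST shifts.
* **Capture correction**: when daylight capture is below 0.90, AOT40 is
  multiplied by (possible daylight hours / valid daylight hours). The
  correction prevents a cumulative index from being biased low by gaps;
  it never reduces the measured value, and at exactly 90% capture the
  value passes unchanged.
* **AOT40 validity**: below 75% daylight capture the station is excluded
  rather than corrected — the same threshold the seasonal mean uses.
* **Afternoon window**: 12:00–18:00. The afternoon mean and the
  **afternoon increment** (afternoon mean − whole-day mean) feed the
  afternoon-regression methods; the increment shrinks with altitude
  because mountain sites see a flatter diurnal cycle.

## Interpolation methods

All methods share a `fit`/`predict` surface over a station-metric table
(projected km coordinates, altitude in m) and use a global
neighbourhood: with ~24 stations, search radii would only add unstated
parameters. Duplicate station coordinates are rejected, never jittered.

**Measured-data-only methods.**

* *IDW* — weights ∝ d⁻ᵏ, k = 2 by default; a target coinciding with a
  station returns that station's value; predictions are convex
  combinations of the data.
* *RBF* — exact interpolation Ẑ(s₀) = Σ wᵢΦ(d₀ᵢ) + w_{n+1}, with the
  weights solving the (n+1)-dimensional system Σⱼ wⱼΦ(dᵢⱼ) + w_{n+1} =
  Z(sᵢ) together with the side condition Σ wⱼ = 0, which determines the
  constant term and makes the interpolator reproduce constant fields
  exactly. Default kernel: thin-plate spline Φ(d) = d² log d (the
  two-dimensional minimum-curvature spline); multiquadric and Gaussian
  kernels are available, with shape parameter defaulting to the median
  nearest-neighbour distance.
* *OK* — ordinary kriging. The semivariogram is estimated by the
  method-of-moments on 10 distance bins up to half the maximum pairwise
  distance, then a model family (spherical default; exponential and
  gaussian available) is fitted by pair-count-weighted least squares.
  The fit runs in normalized (γ/γ_max, h/h_max) units so convergence is
  independent of the metric's scale (γ is ~10¹ ppb² but ~10⁷ (ppb.h)²).
  If the fit fails, a deterministic fallback is used and logged:
  spherical, nugget 0, sill = sample variance, range = half the maximum
  distance. Kriging weights solve the augmented system with the
  unbiasedness constraint Σλ = 1; predictions are computed one
  matrix-vector solve per target so batch and single-point calls agree
  bit for bit.

**Altitude-aware methods.** Altitude is the sole auxiliary covariate.

* *LR* — ordinary least squares of the metric on altitude.
* *LR+res_IDW / RBF / OK* — the regression prediction plus a spatial
  interpolation of its station residuals; with OK this is regression
  kriging, the configuration that wins on altitude-dominated fields.
* *ALR* — ordinary kriging of the afternoon means minus an altitude
  regression of the afternoon increment, converting an afternoon surface
  into a whole-day estimate.
* *ALR+res_IDW / RBF / OK* — ALR plus interpolated residuals of the
  whole-day metric at the stations.

For AOT40F the ALR family interpolates the afternoon-window AOT40
analogue (computed and capture-corrected like AOT40F itself) and
regresses the difference on altitude — the direct structural transfer of
the concentration version; no published description of this adaptation
exists, so it is a package convention.

## Cross-validation and ranking

LOOCV refits the *complete* method — regression and variogram included —
on each reduced network by default; a switch freezes the all-station
variogram across folds instead (arguably what GIS packages do; both
modes are logged). RMSE follows the usual definition; **relative
uncertainty** is 100·RMSE divided by the network mean of the measured
metric, displayed as a whole percent rounded half-up. Methods are
ranked on the RMSE averaged across periods, competition style (ties
share the lowest rank; the next rank is skipped). Ties are detected at
display precision — 2 decimals for ppb, integers for ppb.h — because
that is the precision at which comparison tables are read.

## Synthetic study conditions

The generator emulates a national-scale rural network; its defaults are
the regime the analysis is designed for, and they were fixed as design
choices, not fitted to any test outcome:

| parameter | default | meaning |
|---|---|---|
| domain | 280 × 280 km, 10 km grid | ~78 400 km², desk-scale grid |
| stations | 24, biased uphill (weight e^{2·alt/alt_max}) | sparse, mountain-heavy network |
| intercept / slope | 36 ppb / 0.01 ppb·m⁻¹ | strong linear altitude trend |
| residual field | exponential, sill 4 ppb², range 50 km | smooth regional departure |
| terrain | 35 km broad + 8 km fine relief, logistic onto [0, 1300 m] | rugged, border mountains |
| afternoon increment | 6 ppb at sea level, −0.004 ppb·m⁻¹ | flatter cycle at altitude |
| hourly noise / missingness | 4 ppb white, 5% (random or block) | instrument noise, outages |

The true field is *intercept + slope·altitude + ε(s)* with ε a zero-mean
Gaussian random field simulated exactly by Cholesky factorization (with
an eigenvalue-clipping fallback for numerically semidefinite smooth
covariances). Hourly series add a cosine diurnal cycle peaking
mid-afternoon, exactly zero-mean over each day, with per-station
amplitude scaled so the afternoon increment matches its target — hence a
full-capture noise-free series averages back to the true seasonal mean
bit-exactly, the round-trip the tests exploit. The fine-scale terrain
component keeps altitude varying below the station spacing; this is
what makes the field altitude-dominated (regression r² ≈ 0.7) so that
the regression family outperforms purely spatial interpolation, while
the correlated residual gives the residual-kriging stage a real signal.

What the generator does *not* emulate: weather-driven ozone chemistry,
inter-annual meteorology, spatially structured missingness, non-Gaussian
measurement error (the error law is unreported in the literature; white
Gaussian noise is an assumption), or cross-border station support.
Passing tests therefore demonstrate the statistical machinery and the
relative behaviour of methods under the stated conditions, not absolute
uncertainties of any real network.

A fast path (`station_metrics_from_truth`) draws station metrics
directly from the truth field plus the averaging-noise standard error;
it is distributionally equivalent to running the hourly pipeline at full
capture (and exactly equal in the noise-free limit, which is tested) and
is used in replicate experiments where hourly simulation would dominate
runtime. Replicate counts in the shipped experiments (50 networks for
ordering statistics, 100 for slope recovery) were sized to keep the full
suite around two minutes on one CPU.

## Numerical conventions and degenerate inputs

* Exponential/gaussian variograms use the direct scale parameter,
  γ(h) = nugget + psill·(1 − e^{−h/a}); the generator uses the matching
  covariance, so fitted ranges are comparable to configured ones.
* γ(0) = 0 by convention; the nugget acts at any positive lag, so
  kriging remains an exact interpolator at stations when nugget-free.
* Station order never affects results: cross-validation sorts stations
  canonically before folding.
* Zero-area domains, non-positive grid steps, missing fractions outside
  [0, 1), negative thresholds, zero altitude variance, coincident
  stations, empty prediction sets and all-nodata surfaces are rejected
  with explicit errors.
* A LOOCV fold whose fit fails is excluded from the RMSE, counted, and
  logged; variogram fallbacks are logged at warning level, since silent
  fallbacks are the main reproducibility hazard in geostatistics.

## Known limitations

* Single-realization variogram estimates over a domain only a few
  correlation lengths wide are heavy-tailed; parameter-recovery claims
  hold for the median over replicate fields, not per realization.
* The two printed-table ranks that differ only beyond display precision
  cannot be distinguished by the display-precision tie rule (see the
  ranking section); the headline tie pattern is unaffected.
* Raster I/O covers ESRI ASCII grids only; no reprojection or
  aggregation is performed — the covariate grid must already be on the
  target grid and CRS.
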