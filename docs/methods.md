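# Methods

This note documents the statistical machinery in `sedtemp`: what the model
is, how it is estimated, what the synthetic-data generators do and do not
emulate, and the numerical and design choices that were genuinely open.

## Outcome construction

The outcome is daily percent sedentary time, `Y = 100 * S / T`, where `S`
and `T` are sedentary and total awake minutes for one child-day. Raw input
is a triaxial count stream at 10-second epochs. Processing order:

1. **Non-wear** ("spurious" time): maximal runs of exactly-zero counts of
   length ≥ 20 minutes (120 epochs) on the x-axis signal; configurable
   alternatives are 30 minutes and/or the vector magnitude
   √(x²+y²+z²). A single non-zero epoch breaks a run — no tolerance
   window, because the definition is stated in terms of *consecutive*
   zeros. Runs truncated by the recording edges still qualify (symmetric
   treatment of an unstated case).
2. **Sleep** intervals (diary/algorithm output) are removed next; label
   precedence is non-wear > asleep > awake, so an epoch inside both a
   sleep interval and a zero run counts as non-wear.
3. **Classification**: awake epochs are sedentary iff the x-axis count is
   ≤ 356 per 10-s epoch (a wrist cut-point calibrated for 4–6-year-olds).
   Classification always uses the x-axis count, even when non-wear
   detection uses the vector magnitude, because the cut-point is defined
   on the x-axis only.
4. **Day records**: day boundaries are local civil midnight; `T` counts
   awake epochs, `S` sedentary awake epochs.
5. **Validity**: a day is valid with ≥ 600 awake minutes; a child is kept
   only if the valid days include ≥ 3 weekdays and ≥ 1 weekend day
   (all-or-none per child). The strict profile uses ≥ 720 minutes and
   ≥ 5 valid days in total. "Recorded activity" is interpreted as awake
   wear time (post sleep/non-wear removal); this interpretation is a
   config switch (`min_minutes`), since the phrase is ambiguous between
   awake wear and all wear. Weekend means Saturday/Sunday; school
   holidays affect only the school-day covariate, not validity counts.

## Exposures

* **Temperature**: either a containing-cell lookup on a daily 1-km grid
  or the geodesically nearest station's record; diurnal variation is
  always recomputed as `tmax − tmin`. A point on a shared cell corner
  deterministically belongs to the north-east cell; equidistant station
  ties go to the smaller station id.
* **Precipitation**: inverse distance weighting over ground monitors with
  weights ∝ d^(−p), p = 2 by default (the power is configurable; sources
  describing the method typically omit it). A station within 1 m returns
  its value exactly.
* **NDVI**: mean of the seasonal raster cells whose centres fall within a
  250 m buffer of the home (variants: the containing 30 m pixel, or
  500 m). Seasons: cold-dry Nov–Feb, warm-dry Mar–Apr, rainy May–Oct.
* **Daylight**: NOAA solar-position equations with sunrise/sunset zenith
  90.833° (refraction + solar semidiameter); duration is evaluated at the
  home coordinates on the wear date, with no elevation correction.
  Latitudes poleward of 66° are rejected rather than approximated.
* **Geodesy**: all distances use a local equirectangular approximation;
  over a ≤ 50 km metropolitan area the scale error is < 0.1%, far below
  any exposure gradient of interest.

## The additive mixed model

Design matrix blocks: an intercept; linear columns (categoricals as
reference-coded dummies); penalized spline blocks; and participant
indicator columns with a ridge (identity) penalty, which is exactly a
Gaussian random intercept with σ_u² = σ²/λ_u.

* **Cyclic cubic spline** (day of year, k = 10, period [1, 366] so leap
  years wrap): value/first/second-derivative continuity at the wrap point,
  integrated-squared-second-derivative penalty via the natural-spline
  tridiagonal system. The sum-to-zero constraint is absorbed by a
  null-space reparameterisation, leaving k−2 coefficients and a full-rank
  penalty: at λ → ∞ the term vanishes entirely.
* **Thin-plate regression splines**: kernel |r|³/12 (1-D, linear null
  space) and r² log r/(8π) (2-D, null space {1, x, y}); knots at the
  (possibly thinned) unique covariate values; the kernel matrix is
  projected off its polynomial space, eigen-truncated to the requested
  rank, and the polynomial intercept is absorbed by column centring, so
  the unpenalized null space (the linear trend / the plane) survives
  smoothing. Wing columns are rescaled to unit RMS with the scale
  absorbed into the penalty — pure conditioning, no change to the fit.
* **Basis dimensions**: k = 10 for 1-D smooths and k = 30 for the spatial
  surface by default, exposed in the model builders; the fits are
  insensitive to k well before these values at this data size.

**Estimation.** For fixed log-smoothing-parameters ρ the fit is penalized
least squares. ρ (all penalties, including the random-intercept block) is
chosen by restricted maximum likelihood: with σ² profiled out, the REML
score is minimised by L-BFGS-B over a box ρ ∈ [−18, 22] with an *analytic*
gradient (envelope theorem for the residual term, trace identities for the
log-determinants). The random-intercept block is handled by a Schur
complement on its diagonal cross-product, so a fit with 559 participants
costs tens of milliseconds; a dense path exists and is tested to agree
with the Schur path. GCV is available as an alternative criterion. A fixed
ridge of 1e−8 times the mean design cross-product diagonal keeps the
normal equations well posed under concurvity (daylight is a smooth
function of day of year, so the unpenalized daylight column lies almost
inside the cyclic block's span); the ridge is constant in ρ, so the
gradient stays exact, and it sits ~8 orders of magnitude below the data
scale.

**Inference.** Coefficient covariance is the Bayesian posterior
σ̂²(XᵀX + Σλ S)⁻¹ plus a first-order smoothing-parameter-uncertainty
correction J V_ρ Jᵀ, where J = ∂β̂/∂ρ (available in closed form) and V_ρ
is the inverse REML Hessian over the interior smoothing parameters —
the analogue of requesting the unconditional covariance from standard GAM
software. 95% intervals are estimate ± 1.96·SE; Monte-Carlo checks in the
test suite put their empirical coverage for linear terms at roughly
93–95% under the generator's Gaussian model. Per-term effective degrees
of freedom are the trace of the corresponding hat-matrix block;
AIC = −2·loglik + 2·(total EDF + 1). Wald-type F statistics for smooths
use the pseudo-inverse of the term's covariance at rank round(EDF); no
exact reference distribution exists for penalized fits, so their p-values
are indicative, not exact.

**Smooth-vs-linear comparison** fits both variants and compares AIC, ties
preferring the linear model. Under a truly linear effect the smooth's EDF
collapses to ≈ 1 (its unpenalized linear direction); REML occasionally
(order 10% of replicates at this data size) finds a shallow interior
optimum with spurious wiggle, a behaviour shared by reference GAM
software on identical data, which is why the test suite evaluates the
typical (median-over-replicates) behaviour and bounds the rate of
*material* false preference (AIC improvement > 2).

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions for every calibration and
recovery experiment:

* **Cohort** (n = 559 default): age truncated-normal on [4, 6.99] with
  mean 4.8, SD 0.5 (parent parameters solved numerically so the truncated
  moments match); 51% male; maternal education 39.9/36.5/23.6%
  (<HS/HS/>HS); BMI z ~ N(0.2, 1.1²); homes uniform in a Mexico City
  bounding box.
* **Weather**: sinusoidal seasonal means plus AR(1) anomalies (φ = 0.7)
  for daily mean temperature (15.4 °C, seasonal amplitude 1.8 °C peaking
  in May) and diurnal range (11.9 °C, amplitude 2.0 °C peaking in the dry
  winter); `tmax = tmean + 0.563·diurnal`, `tmin = tmax − diurnal`, so
  tmin ≤ tmean ≤ tmax holds by construction and the implied means are
  22.1/15.4/10.2 °C. Anomaly series of ≥ 180 days are recentred on zero,
  making realised long-run means equal the configured climatology (the
  generator's contract). Precipitation is hurdle-gamma, wet-day
  probability 0.65 in the May–October rainy season and 0.10 otherwise,
  giving ≈ 2.8 mm/day overall. The generated SDs (≈ 2.0–2.3 °C) sit
  slightly below the cohort's printed 2.2–2.5 °C — means, not SDs, are
  the calibration targets.
* **Sampling**: one ~7-day wear window per child, start dates weighted by
  the campaign's uneven monthly person-day distribution (April-heavy,
  Nov–Jan trough). Because of this weighting, person-day expectations of
  seasonal covariates differ from annual means; the outcome intercept is
  anchored on numerically computed *person-day* expectations so the
  default outcome mean lands on 56.0%.
* **Sleep**: night sleep N(450, 60²) minutes starting ≈ 21:00 the prior
  evening (crossing midnight), plus a 35%-probability afternoon nap of
  N(57, 20²) minutes: 470 min/day in expectation.
* **Outcomes**: the day-level path draws
  Y = α + βᵀx + f(x) + u_j + ε_ij, clipped to [0, 100], with defaults
  σ_u = 4.0, σ_e = 4.5 so the total SD is ≈ 6 (the decomposition is a
  generator choice; the emulated summary statistics report only the
  total). The epoch-level path emits a two-state sedentary/active Markov
  chain whose stationary occupancy equals the same linear predictor
  clipped to [1, 99]%, with geometric dwell times (mean regime-exit scale
  12 epochs = 2 min — within-day autocorrelation is not identified by a
  day-level analysis, so this is an exposed artifact choice), sedentary
  x-counts uniform on [0, 356], active on [357, 3000], low non-zero
  counts during sleep, and Poisson-inserted zero-count non-wear runs of
  20–180 minutes that exercise both detector thresholds.

Passing tests on these data show the pipeline and estimator are correct
*under the stated generating model*: Gaussian day noise, linear planted
effects, exchangeable children, exposure series shared city-wide with a
smooth deterministic spatial anomaly. They do not establish robustness to
device-specific count artefacts, non-Gaussian outcome tails, informative
missingness/non-wear, within-week behavioural structure, or residual
spatial confounding — none of which the generator emulates.

## Problem sizes

Default experiment sizes were chosen so the full chain is exercised at the
emulated study's scale: recovery and hypothesis-test simulations use 559
children × 6 days (≈ 3,350 child-days) with 20–60 Monte-Carlo replicates;
generator calibration checks use ≥ 5,000 child-days; the weather
climatology check uses ten simulated years; epoch-level consistency checks
use ~250 full simulated child-days (≈ 2 × 10⁶ epochs). A full-model fit at
study scale takes well under a second, so the entire suite runs in a few
minutes on one core.

## Known limitations

* Gaussian identity-link model only (as in the analysis it implements);
  no random slopes (kept out deliberately — the emulated analysis found
  them immaterial), no non-Gaussian families.
* Smooth-term p-values are approximate Wald constructions.
* The equirectangular geodesy and containing-cell grid assignment are
  city-scale choices; do not reuse at continental scale.
* The epoch simulator's count magnitudes are calibration devices for the
  ≤ 356 dichotomy, not a biomechanical model of wrist acceleration.
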