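# sedtemp

Does day-to-day ambient temperature shift how much of their waking time
young children spend sedentary? `sedtemp` is a Python package for answering
that kind of question with wrist-accelerometer cohorts: it turns raw
10-second epoch count streams into valid child-day percent-sedentary
records, assembles residential environmental exposures (daily temperature
metrics, inverse-distance-weighted precipitation, NDVI greenness buffers,
NOAA daylight hours, school-day classification), and fits penalized-spline
Gaussian additive mixed models with participant random intercepts. It is
aimed at physical-activity epidemiologists who want the whole chain —
epoch cleaning rules, exposure coding, and the mixed additive model — in
one tested, scriptable place.

Because cohort accelerometry is rarely shareable, the package also ships
calibrated synthetic-data generators (cohort, weather, sleep, raw epoch
streams, day-level outcomes) whose defaults emulate a 559-child Mexico
City cohort: mean daily sedentary time 56.0% of awake time (SD 6), daily
maximum temperature averaging 22.1 °C, sleep 470 min/day, uneven seasonal
sampling. Effect sizes, variance components and nonlinearities are
plantable, so every stage — including the model's inference — can be
checked against known ground truth.

## The model

For child *j* on day *i*, with percent sedentary time
*Y*<sub>ij</sub> = 100 · *S*<sub>ij</sub>/*T*<sub>ij</sub>
(sedentary over awake minutes), the reference model is

> *Y*<sub>ij</sub> = α + u<sub>j</sub> + **β**ᵀ**x**<sub>ij</sub> +
> f₁(rain<sub>ij</sub>) + f₂(age<sub>j</sub>) + f₃(day-of-year<sub>ij</sub>) +
> f₄(lon<sub>j</sub>, lat<sub>j</sub>) + ε<sub>ij</sub>

with u<sub>j</sub> ~ N(0, σ<sub>u</sub>²) participant random intercepts,
ε<sub>ij</sub> ~ N(0, σ²), linear covariates **x** (one temperature metric
per model — maximum, mean, minimum, or diurnal variation — plus NDVI,
daylight, sleep, BMI z, sex, maternal education, school-day class), a
thin-plate spline for rain and age, a cyclic cubic spline (period 366) for
day of year, and a 2-D thin-plate surface for the home location. All
smoothing parameters, including the random-intercept precision, are chosen
by REML; random intercepts are estimated as a ridge-penalized indicator
block, which is exactly the Gaussian mixed-model formulation with
σ<sub>u</sub>² = σ²/λ<sub>u</sub>.

Raw epoch processing follows standard paediatric wrist-actigraphy rules:
non-wear is ≥ 20 (or 30) consecutive minutes of zero x-axis (or vector
magnitude) counts; awake epochs are sedentary iff the x-count is ≤ 356 per
10-s epoch; days need ≥ 600 awake minutes and children ≥ 3 valid weekdays
plus ≥ 1 weekend day (a stricter 720-min / 5-day profile is available).

## Worked example

Simulate a 200-child study with the default calibration (which plants a
−0.26 %-per-°C maximum-temperature effect), process it and fit the four
temperature models:

```bash
sedtemp run-study --n-children 200 --seed 11 --out demo_out
```

```
artifacts in demo_out
  tmax: -0.257 %/unit (95% CI -0.432, -0.081)
  tmean: -0.302 %/unit (95% CI -0.505, -0.099)
  tmin: -0.210 %/unit (95% CI -0.390, -0.030)
  diurnal: -0.060 %/unit (95% CI -0.243, +0.122)
```

The planted maximum-temperature effect (−0.26% of awake time per °C) is
recovered as −0.257 with a confidence interval excluding zero; the other
metrics pick up correlated shares of the same planted signal, which is why
such studies fit one temperature metric per model. `demo_out/` contains a
cohort summary table, per-model coefficient tables and summaries,
univariable fits, the smooth-vs-linear AIC comparison, a one-at-a-time
sensitivity grid (non-wear coding, NDVI buffer, inclusion criteria,
temperature source) and a reproducibility manifest. At the cohort's mean
awake time (846 min/day), a −0.26 %/°C coefficient is about 2.2 fewer
sedentary minutes per degree (`minutes_equivalent(-0.26, 846.4)` →
−2.20).

The same model is available as a library object, statsmodels-style:

```python
from sedtemp import AdditiveMixedModel, sedentary_model_spec, generate_daily_dataset

data, truth = generate_daily_dataset(n_children=559, n_days=6, seed=1)
result = AdditiveMixedModel(data, sedentary_model_spec("tmax")).fit()
print(result.summary())          # coefficients, CIs, per-smooth EDFs, sigma_u
result.plot_smooths()            # fitted smooth panels with 95% bands
```

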