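# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline runs them.

## Chamber flux estimation

The closed dynamic chamber raises its internal CO₂ mixing ratio linearly
while leakage and dilution are negligible; the efflux follows from the
ideal gas law, Rs = P·V1·(∂c/∂t)/(R·T·V2).  The slope is an ordinary
least-squares fit of the 1 Hz mixing ratio on time.  Fit diagnostics are
kept with every estimate: the slope's standard error, the R² of the trace
fit, and a quality flag (`low_r2` below a configurable threshold, default
0.9; `negative_slope` for declining traces, which are computed but
excluded from downstream regressions by default).  An optional deadband
discards the first k seconds of a trace (default 0) for chamber-closure
artefacts.

Segment geometry uses two orthogonal diameters: volume is the elliptical
cylinder π·(d1/2)·(d2/2)·L.  The lateral surface uses the mean-diameter
cylinder π·(d1+d2)/2·L rather than an elliptic perimeter — the two differ
by <1 % at the eccentricities band dendrometer sprouts show (d2/d1 within
roughly 0.9–1.1), and the circular limit keeps the exact surface/volume
ratio 4/d.  End faces are excluded (sealed by the chamber).  V1 is taken
as a supplied per-measurement system volume; no automatic subtraction of
the enclosed sprout volume is performed unless the caller does so.

### Q10 normalization

R_ref = Rs · Q10^((T_ref − Ts)/10): a measurement one full decade warmer
than the reference is scaled down by the factor Q10 (default 2, a typical
oak-species value), so summer readings are *normalized*, not inflated.
The opposite sign convention — the factor multiplying instead of dividing
— circulates in the literature; it is available as `literal_exponent=True`
for comparison.  The reference temperature defaults to 15 °C (hence R15)
and is configurable, e.g. to 10 °C.

## Zero-growth partitioning

With M(t) the running maximum of the diameter series, GRO = M − d(0) and
TWD = M − d(t): growth is credited only when the stem exceeds its previous
maximum; every excursion below it is counted as water deficit.  Choices
the concept itself leaves open:

* **Initialization.**  TWD(first) = GRO(first) = 0: the running maximum
  starts at the first observation.
* **Gaps.**  The running maximum carries across observation gaps (the stem
  does not reset); daily statistics on days touching a gap longer than a
  threshold (default 6 h) are null, as are days with no observations and
  the increment of the day following a nulled day.
* **Days and increments.**  Local-time calendar days; the daily increment
  is GRO at the day's last observation minus GRO at the previous day's
  last observation.  At hourly resolution this differs from midnight
  interpolation by at most one hour of growth.
* **Moving averages.**  The 7-day averages of daily increment and daily
  TWD maximum are centered (a trailing option exists) and need at least 4
  non-null days in the window.
* **Sensor jumps.**  Steps faster than 500 µm/h (configurable) are
  flagged, never auto-corrected.

The reconstruction identity d = d(0) + GRO − TWD is exact in real
arithmetic; in floating point it is bit-exact whenever all readings share
a common dyadic quantum, which fixed-resolution sensor output satisfies.
The test suite therefore checks bit-exactness on sensor-quantized random
walks (quantum 2⁻¹⁰ µm) and value-equality elsewhere.

## Micromet derivations

VPD uses the Magnus saturation-pressure form with coefficients 0.6108 kPa,
17.2694 and 237.3 °C.  The coefficient set yields kPa; output defaults to
hPa (×10), with `units="kpa"` exposing the raw value, since both units are
used in the field.  RH outside [0, 100] is a validation error; Ta at or
below −237.3 °C (the denominator zero) is a domain error.

Deep soil water content lost to a sensor outage is reconstructed from a
shallow co-located sensor by OLS of deep on shallow, fitted separately per
treatment plot on pairs matched to the nearest timestamp within ±30 min
(configurable).  Predictions are clipped to the physical [0, 100] % range
and flagged as estimated.  Gaps without shallow support stay null — the
micromet module never interpolates in time.

## Drought-effect analysis

All regressions consume campaign/plot mean values (per species, plot and
date), computed after dropping negative-slope flux estimates.  The
reference-year Rs–temperature relationship is fitted linearly and as a
log-linear exponential; the exponential's R² is evaluated on the original
scale so the two models are comparable.  Each drought-year campaign mean
is expressed as a residual from, and a percentage of, the linear reference
prediction at its stem temperature; means ± SD are taken across the four
plots per date.  Points whose predicted efflux is non-positive (possible
below ~11.7 °C with oak-like coefficients) are excluded from the percent
summary with a warning.

The species comparison of R15 against the mean stem increment rate is a
single OLS with a species indicator, the rate, and their interaction —
mathematically the classical ANCOVA; the indicator and interaction
coefficients are the intercept and slope differences with t-tests.
`ratio_at_rate` expresses R15 at a given increment rate as a percentage of
the zero-increment (maintenance-respiration) level.  Pearson correlations
of per-sprout R15 with sprout diameter and with the 7-day mean increment
are computed per campaign; p-values are two-sided throughout and no
multiple-testing correction is applied (inference is at α = 0.05).

Mixed-effects models (random intercepts for tree and measurement day) are
deliberately not fitted here; the pipeline exports the long-format table
(`mixedmodel_input.csv`, with thinning/throughfall-reduction indicators
decoded from the plot labels) that standard mixed-model tooling consumes.

## Synthetic-data generator

The generator emulates the study conditions every test assumes: 4
treatment plots (C-0, T-0, C-r, T-r) × 2 species × 6 sprouts, hourly
records April–October, six campaigns in the wet year and four in the
drought year, measured in the plot order C-0 < T-0 < T-r < C-r (expressed
as small stem-temperature offsets, 0–2.4 °C).

* **Micromet.**  Ta is a seasonal plus diel sinusoid with smooth daily
  noise; RH is anticorrelated with Ta; precipitation is a marked Poisson
  process.  SWC follows a bucket: rain refill saturating toward 35 %,
  VPD-proportional drawdown toward a 3 % residual.  Drought years get a
  rainless July–August with +3 °C and −12 % RH, driving summer SWC below
  10 %.  The first wet year masks deep SWC before 10 July and provides
  shallow manual readings on campaign mornings, related to the deep sensor
  by deep = 0.8·shallow + 3 (+0.3 % noise), so the calibration stage has a
  truth to recover.
* **Growth.**  The seasonal increment rate is the sum of two Gaussian
  pulses in day-of-year (peaks near day 166/152 for oak/hornbeam at
  150/130 µm day⁻¹, and day 240 at 120 µm day⁻¹, widths 12/10 d) — the
  simplest shape giving the observed double peak and a wet-year annual
  increment near 7.5/6.9 mm.  Drought years halve the amplitudes and
  additionally multiply the rate by the suppression factor f inside the
  window.  Sprouts carry a lognormal growth multiplier (σ = 0.15).
* **Stem water.**  Diel shrinkage is zero at 06:00 and maximal at 18:00,
  with amplitude proportional to the day's mean VPD (nominal 35 µm oak /
  20 µm hornbeam at 10 hPa, bounded ×0.2–2.5); drought years add a
  sustained shrinkage ramping to 250/70 µm over the window and relaxing
  with a 15-day constant.  Observation noise is N(0, 2 µm).
* **Fluxes.**  True campaign efflux is (slope·Ts + intercept) per species
  (defaults 23.3/−271.5 oak, 30.5/−374.2 hornbeam), times f on
  drought-window dates, times mean-one lognormal multipliers: per plot
  (σ = 0.08), per sprout (σ = 0.25, fixed across campaigns, matching the
  "highly variable among sprouts" character of such data), and per
  measurement (σ = 0.05), floored at 5 µmol m⁻³ s⁻¹.  Chamber traces
  invert the flux equation exactly (slope = Rs·R·T·V2/(P·V1)) and add
  0.5 ppm Gaussian noise at 1 Hz over 60 s from 420 ppm.
* **Determinism.**  One seeded generator stream, fixed draw order:
  identical seeds give byte-identical bundles.

The noise scales above are the package's own order-of-magnitude choices —
field studies rarely publish within-plot variance components — and they are
deliberately *not* tuned: tests assert recovery under these conditions.
What the generator does **not** emulate: chamber leakage and non-linear
trace curvature, corticular photosynthesis, sap-flow CO₂ transport,
spatial SWC heterogeneity, sensor drift, and winter dynamics (each season
restarts at a fresh dendrometer zero).  Passing tests therefore
demonstrate correctness of the computational chain under the stated
statistical structure, not robustness to those field artefacts.

## Problem sizes and numerical choices

The default scenario (48 sprouts × 2 seasons hourly, 480 chamber traces)
runs end-to-end in a few seconds; tests use it directly, with Monte-Carlo
loops of 1,000–2,000 replicates where sampling distributions are asserted.
Regression engines are scipy/statsmodels OLS; tests verify them against
closed-form normal equations at 1e-10.  Degenerate inputs have defined
behaviour rather than NaN surprises: flat traces give slope 0 with a
`low_r2` flag, flat regression responses report R² = 0 with a
`flat_response` flag, zero-variance predictors and <2-point fits raise
typed errors, and Q10 ≤ 0 and RH outside [0, 100] are rejected.

## Known limitations

* The zero-growth concept attributes osmotic or thermal diameter changes
  to water deficit; no temperature correction of the band is applied.
* The exponential temperature fit is log-linear OLS, not nonlinear least
  squares; with multiplicative errors this is the natural estimator, but
  the two differ for additive noise.
* Percent-of-expected is undefined where the linear reference predicts
  non-positive efflux; such points are excluded, which can bias cold-date
  summaries if they were common (they are flagged and counted).
* The drought window, like the suppression factor, is a scenario input;
  the analysis does not detect drought onset from the data.
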