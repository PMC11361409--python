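# Methods

`classair` analyses the kind of paired indoor/outdoor monitoring campaign
used to evaluate a portable HEPA air cleaner in school classrooms: 10-s
instrument time series of CO₂ (ppm), ultrafine-particle number
concentration (#/cc, total and per size bin) and black carbon (µg/m³),
recorded for ~24 h before and ~24 h after the cleaner is switched on. This
note describes the models, the estimators, the synthetic-data generator
used to validate them, and the numerical and design choices that were
genuinely open.

## Single-zone mass balance

All particle analyses rest on the well-mixed single-zone balance

    dC_in/dt = P·a·C_out − (a + k_dep + CADR/V) · C_in

with penetration factor `P` (dimensionless, fraction of outdoor particles
surviving the envelope), outdoor air-exchange rate `a` (1/h), surface
deposition `k_dep` (1/h), clean-air delivery rate `CADR` (m³/h, zero when
the cleaner is off) and room volume `V` (m³). At steady state the
indoor/outdoor ratio is

    I = P·a / (a + k_dep + CADR/V)

which is the model-implied infiltration factor. Assumptions: no indoor
particle sources, perfect mixing, first-order losses only; HVAC
recirculation filtering is lumped into `k_dep`. Multi-zone transport and
size-distribution dynamics (coagulation, growth) are out of scope.

## Air-exchange rate from CO₂ decay

CO₂ is raised well above ambient (dry ice, mixing fans), sources are
removed, and the excess decays at the outdoor air-exchange rate because a
gas tracer sees neither deposition nor the HEPA unit:

    C(t) = C_bg + A₀ · exp(−k·Δt),   A₀ = C_peak − C_bg.

`CO2DecayModel.fit()` estimates `(A₀, k)` by nonlinear least squares over
the decay window with `C_bg` held fixed at the mean of the ambient outdoor
CO₂ series over the same window (fallback 420 ppm when no ambient series
exists). Fixing the background rather than fitting it avoids the strong
`C_bg`–`k` trade-off at short windows; the quantity being fitted is the
measured in-room CO₂ minus ambient. A log-linear slope on `ln(C − C_bg)`
is reported as a cross-check; the two agree within 2% on exact-model data.

Protocol diagnostics follow the field procedure: `elevation_check` (peak ≥
4× background, boundary inclusive), `check_uniformity` (two room monitors,
rolling 5-min relative spread ≤ 10% — the protocol says only "equivalent
or very similar", 10% is our operationalisation), and an adequacy flag
(elevation must have fallen to ≤ 1/3 of its start; `ln 3 / k` hours are
needed, so slow rooms are flagged when the window is short). Samples at or
below background are excluded; fewer than 10 usable samples is an error.

## Infiltration and ratio-based effectiveness

Infiltration is computed on aligned 30-min window means (half-open
windows, boundaries on whole multiples of the window length from
midnight): per-window ratio indoor/outdoor, aggregated by the mean (median
reported alongside). Windows with outdoor means below a floor (50 #/cc for
number concentrations, 0.05 µg/m³ for BC) are excluded to keep
denominators away from zero; ratios are not capped at 1, since indoor
sources can push them above it. 95% CIs are nonparametric bootstrap over
windows (2000 resamples, seeded). Fewer than 4 usable windows is an error.

Removal effectiveness compares HEPA-on to HEPA-off infiltration:

    E = 1 − I_on / I_off,

with a CI from jointly resampling both sets of window ratios. The
before/after contrast is tested with a one-sided Wilcoxon rank-sum
(exact null for combined n ≤ 20 without ties, tie-corrected normal
approximation otherwise), and indoor–outdoor coupling is summarised by
Pearson correlation of aligned window means. `lag_persistence` tracks a
rolling 30-min correlation at 5-min steps after the cleaner switches off.

## Regression-based effectiveness

The lagged log-log model pools windows across sessions and schools:

    log C_in(t) = β₀ + β₁ · log C_out(t − 30 min) + β_H · HEPA + School

fitted by OLS with school as categorical fixed effects (reference: first
school alphabetically) and natural logs. The 30-min lag matches the
observed delay between outdoor and indoor peaks. Rows with nonpositive
means are dropped before the log transform and counted; a session losing
more than 20% of rows is flagged (rooms with many zero indoor windows can
be excluded wholesale by the caller, mirroring the field analysis). β₁ is
estimated, not fixed at 1.

`exp(β_H)` is the multiplicative indoor reduction while the cleaner runs,
so regression effectiveness is `1 − exp(β_H)`, with a CI from transforming
the normal interval for β_H. Predictions at a fixed outdoor level
(default 5000 #/cc, the campaign's median) propagate the coefficient
covariance through the linear predictor and exponentiate.

Two known, genuine properties of this estimator on noisy data: measurement
noise in the outdoor regressor attenuates β₁ toward zero
(errors-in-variables), and the prediction is consistent for the
*conditional* mean given the observed lagged outdoor window, not for the
noise-free physical ratio. The test suite therefore checks CI coverage of
the physical steady state in the exact-pairing regime (clean, slowly
varying outdoor driver) and checks the effectiveness estimator — which is
insensitive to the slope — under full noise.

## Flight-operations geofence

A flight counts toward a school's exposure when any track point is
strictly below 750 m altitude and strictly within one mile
(1609.344 m) of the site, each flight id at most once per site. Distances
are haversine great-circle with Earth radius 6371.0088 km. Altitude is
taken as supplied in the input (AGL vs MSL is a pass-through). Per-site
counts are tabulated by airport and operation and summarised across sites
by median and 25th–75th percentiles (linear interpolation).

## Synthetic-data generator

The generator provides ground-truthed inputs for every stage:

* **Outdoor driver** — baseline + sinusoidal diurnal traffic cycle +
  Poisson-arriving exponential aircraft plumes + multiplicative lognormal
  scatter. Defaults: 5000 #/cc baseline (the study-area median outdoor
  level), 1500 #/cc diurnal amplitude peaking mid-morning, 2 plumes/h with
  8000 #/cc peaks decaying at 6/h (~10-min lifetime), 15% CV.
* **Indoor response** — exact per-step exponential update of the mass
  balance (outdoor held constant within a step), so the steady state is
  unbiased by the step size; piecewise-constant CADR over HEPA intervals
  is handled segment by segment. Halving the step changes steady-state
  windowed ratios by well under 0.1%.
* **Measurement model** (`simulate_session`) — the room responds to the
  clean outdoor signal; the recorded indoor and outdoor channels then
  independently receive the multiplicative scatter plus a slow additive
  instrument drift (Ornstein–Uhlenbeck, sd 150 #/cc, 2-h correlation
  time). The drift matters: it does not shrink when the HEPA unit lowers
  the indoor signal, which is what erodes indoor–outdoor correlation
  during an intervention — a purely multiplicative noise model would
  (wrongly, relative to field experience) leave the HEPA-on correlation as
  high as the HEPA-off one.
* **CO₂ experiment** — background hold, linear ramp to `peak_multiple` ×
  background (warning below the protocol's 4×), exponential decay at the
  zone's AER; two room monitors (centre, wall with a configurable relative
  bias, default 2%) with additive Gaussian noise (default 2 ppm; recovery
  tests use 10 ppm); a constant-ambient outdoor series.
* **Flight tracks** — straight-line tracks built in a local tangent plane
  with closest-approach distances and altitudes sampled away from the
  geofence thresholds (≥ 0.15-mile and ≥ 70-m margins), so the stored
  per-flight ground truth cannot flip under great-circle rounding.

What the generator does *not* emulate: indoor particle sources, occupancy,
instrument-specific artefacts (aethalometer loading, NanoScan scan-phase
mixing beyond the uniform 2-min trim), wind-driven infiltration changes,
and non-stationary plume statistics. Passing tests therefore demonstrate
the estimators recover known parameters under the stated noise model, not
that field data meet that model.

Deliberate parameter choices for the recovery suites (package choices, not
fitted quantities): CO₂ recovery uses 100 experiments at rates 0.6, 1.1,
2.2 and 4.4 /h — the span observed across the schools — with 10-ppm noise
and 2-h decay windows; effectiveness recovery uses 50 replicates of 24-h
HEPA-off + 24-h HEPA-on sessions (≈48 windows per arm) in a 250-m³ room
at a = 1.5/h, k_dep = 0.5/h and CADR = 849.5 m³/h (500 CFM × 1.699011),
true effectiveness 1 − 2.0/5.398 ≈ 0.63.

## Numerical and convention choices

* Valve demultiplexing: alternation is indoor-first at the schedule's
  phase origin (configurable); the 2-min head trim applies uniformly to
  every valve-switched channel to keep channels time-aligned.
* CPC substitution applies to the total-particle channel only, matched to
  the nearest usable CPC sample within 30 s; unmatched gaps stay errors.
* Window coverage = usable samples / expected samples at the native
  resolution; windows under 50% coverage are dropped.
* Unit constants: 1 ft = 0.3048 m, 1 CFM = 1.699011 m³/h,
  1 mile = 1609.344 m.
* Bootstrap and simulation randomness always flows through explicit seeds
  (`numpy.random.default_rng`); identical seeds give identical output.
* Degenerate inputs: zero-variance correlation inputs return NaN with a
  warning; fully tied Wilcoxon groups return p = 1 with a warning; a zero
  HEPA-off infiltration makes effectiveness undefined (error).

## Limitations

The ratio and regression estimators assume indoor particles are of
outdoor origin; indoor sources bias infiltration upward. OLS standard
errors ignore the autocorrelation of window means, so bootstrap/delta CIs
are mildly optimistic on strongly drifting data. The CO₂ method estimates
the *outdoor* air-exchange component only, in unoccupied rooms; the decay
rate is reported as the total outdoor AER even though a strict reading of
the fitted constant also absorbs any CO₂ sinks. The geofence count treats
each flight id once per site and does not smooth or deduplicate
multi-segment tracks.
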