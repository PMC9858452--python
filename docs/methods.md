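# Methods

This note records the models, parameter defaults, and numerical choices made
in `gikit`, in enough detail to reproduce or audit any number the package
reports. Problem sizes (schedules, noise levels, replicate counts) are the
package's own validation choices unless stated otherwise.

## 1. Conversion chain

A reducing-sugar assay reading is converted to digestion extent as

```
conc [mmol/L]   = (dA_sample / dA_standard) × standard_conc
maltose [mg]    = conc × aliquot_volume [L] × 342 [mg/mmol] × dilution_factor
starch-eq [mg]  = maltose × 324/342                 (percent-starch basis only)
extent [%]      = mass / substrate_mass × 100
```

with substrate mass = starch mass (dry basis) for the percent-starch basis,
or total carbohydrate mass for the normalized-reducing-sugar basis. Defaults:
aliquot 100 µL, standard 1 mmol/L maltose, dilution multiples 2500
(INFOGEST, 50 × 50) and 750 (single-enzyme, 5 × 150). The two bases differ by
the fixed factor `(324/342) × carb_mass / starch_mass`, which the test suite
verifies numerically. Values above 100% on the starch basis are tolerated up
to 110% (assay overshoot) and flagged, never clipped.

## 2. Kinetic models

- **SK**: `C(t) = C0 + (C∞ − C0)(1 − e^(−kt))`, parameters `(C0, C∞ − C0, k)`.
- **CPS**: `C0 + Σ_j C_j∞(1 − e^(−k_j(t − t_jstart))) · 1[t > t_jstart]`,
  first onset fixed at 0, later onsets free in `(0, t_max)`.

Both are fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`, `trf`, `xtol = ftol = gtol = 1e-14`) with an
analytic Jacobian for SK. Bounds: `C0 ∈ [0, max(values)]`,
amplitudes `∈ [0, 3·max(values)]`, `k ∈ (1e-8, 10]`. Initialization: `C0` from
the first observation, `k` from the LOS slope when available (0.02 /min
otherwise), with multi-starts over `k × {1/√10, 1, √10}` and, for CPS, over
interior timepoints for each onset. Non-convergence returns best-effort
parameters with `converged = False`; the pipeline logs it as a warning.

Noiseless recovery on the 10-point single-enzyme schedule is ~1e-13 (SK) and
~1e-15 (CPS) maximum relative error.

## 3. LOS transform and fraction counting

For each consecutive pair with a positive increment the LOS plot records
`(t_mid, ln(ΔC/Δt))`; non-positive increments are dropped and counted (the
log is undefined there). Linear LOS segments indicate first-order pools with
slope `−k`.

`count_fractions` replaces the usual visual segment count with BIC-selected
segmented regression: 1 or 2 ordered linear segments, breakpoints on observed
midpoints, each segment ≥ 3 points, `BIC = n·ln(WRSS/n) + p·ln(n)` with
p = 2 (one segment) or 5 (two segments + breakpoint); ties break toward fewer
segments. Four statistical guards make the count robust on noisy, unevenly
sampled schedules:

1. **Precision weighting.** Under additive value noise σ, the delta method
   gives `var(ln slope_i) ≈ 2σ²/ΔC_i²`, so points are weighted by their
   increment — plateau points (tiny increments, wild logs) no longer dominate.
2. **Finite-difference bias correction.** A chord slope over width Δ
   overstates the midpoint derivative of an exponential by
   `sinh(kΔ/2)/(kΔ/2)`. On uneven schedules this width-dependent offset
   masquerades as curvature; each segment fit removes it iteratively.
3. **Slope tests.** Each candidate segment must have a significantly negative
   slope (one-sided t, 5%), and the two segments must differ in the
   fast-then-slow direction (one-sided Welch test, Bonferroni-corrected for
   the number of candidate breakpoints). A later segment must also represent
   net digestion progress above the noise floor.
4. **Value-domain confirmation.** A two-segment verdict must additionally
   beat the one-fraction fit by BIC on the raw digestion values (7 vs 3
   parameters). The log transform amplifies plateau noise; this parsimony
   check on the untransformed data vetoes spurious splits.

On the seeded discrimination suite (100 SK + 100 CPS noisy digestograms,
σ = 0.3, truths `(C∞ = 40, k = 0.03)` and
`(30, 0.1, 0) + (20, 0.01, t_start = 30)`), accuracy is 97.5–99.5% across
test seeds. Pooling duplicate replicates into one LOS fit was evaluated and
rejected: the residual plateau tilt is a systematic conditioning artifact
(retaining only positive increments biases small increments upward), so more
points make it *more* statistically visible, not less.

## 4. AUC

The area under the fitted curve over `[0, T]` is closed-form:
`C0·T + Σ_j C_j∞ (span − (1 − e^(−k_j·span))/k_j)` with
`span = max(T − t_jstart, 0)`. Fitting first lets the horizon extend past the
last sampled time (e.g. 180 min on a 120-min schedule). A trapezoidal
cross-check on raw observations refuses to extrapolate and adds a leading
flat segment when `t = 0` is absent; on a dense (0.001-min) exact curve the
two methods agree within 1.2e-9 %.

## 5. Calibration, prediction, screening

Calibration is one-predictor OLS (statsmodels): `GI = a + b·AUCR180`. The
serialized model keeps `(residual SE, n, x̄, Sxx)` so a deserialized model
reproduces the exact new-observation prediction standard error
`s·sqrt(1 + 1/n + (x − x̄)²/Sxx)`; a replicate SD contributes `b·sd` in
quadrature. Models built from published coefficients alone yield predictions
without a model-based SD. Correlation screening reports Pearson r with
two-sided p (t distribution, n − 2 df), starred `**` (p < 0.01) /
`*` (p < 0.05), with an optional Holm correction (off by default). Error
rate is `|eGI − GI|/GI × 100`, reported to 2 dp.

## 6. Synthetic data

Generators evaluate the forward model on a preset schedule
(`SINGLE_ENZYME`: 5…240 min, 10 points; `INFOGEST_INTESTINAL`: 0…120 min,
9 points) and add i.i.d. Gaussian noise truncated at zero, duplicates by
default. `simulate_calibration_study` draws AUCR180 targets uniformly
(default [500, 3500]), draws `k ~ U(0.005, 0.05)`, solves `C∞` so the
analytic 180-min AUC hits the target exactly (C0 = 0), and assigns
`GI = a + b·AUCR + N(0, σ_GI)`. All child seeds derive from one
`numpy.random.default_rng(seed)` stream and stay below 2³¹. Over 500 seeded
studies the end-to-end pipeline recovers the generating intercept/slope
within ~3% / ~0.2% on average.

## 7. Limitations

- The LOS fraction counter supports at most two fractions (the schedules in
  scope cannot resolve more); `max_fractions` is a parameter but untested
  beyond 2.
- The finite-difference bias correction assumes a single exponential per
  segment; the first slow-pool interval after an onset still carries the
  fast pool's tail, so segment slopes are only approximately `−k` near a
  breakpoint (the nonlinear fit, not the LOS slope, is the parameter
  estimate).
- The printed dilution multiples (2500 / 750) are kept as defaults even
  though they disagree with the stated vessel-volume arithmetic; override
  via the config JSON if your protocol differs.
- Calibration assumes a single protocol and basis per run; mixing protocols
  in one calibration table is not prevented beyond the recorded metadata.
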