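# Methods

## Model and scope

`extractkin` treats solid–liquid extraction kinetics phenomenologically:
the solvent-phase concentration X(t) of the extracted analyte (mg per
100 g of solid, time in minutes throughout) is assumed to rise
monotonically from X(0) = 0 toward an equilibrium X_eq, and the shape
of the rise is described by one of five empirical families on the
dimensionless scale X\*(t) = (X − X_eq)/(X_i − X_eq), so that
X(t) = X_eq·(1 − X\*(t)). No mass-transfer mechanism (Fickian
diffusion, film resistance) is modelled; the empirical families are
chosen precisely because each admits a closed-form derivative (for rate
curves) and a closed-form inverse (for process-time prediction), which
a diffusion series solution does not.

All five families satisfy f(0) = 1 except Henderson–Pabis, whose
intercept is its own parameter a (useful when the earliest points sit
off the asymptotic exponential); all are strictly decreasing on t > 0
for parameters in their domains (a > 0, b > 0).

Domain edges handled explicitly:

- **Peleg** approaches the asymptote X\* → 1 − 1/b only as t → ∞, and
  for b < 1 crosses zero at t = a/(1 − b). Inverting to a target at or
  below the asymptote raises `UnreachableConcentrationError`; the
  round-trip identity holds on the positive part of the curve.
- **Henderson–Pabis** never exceeds its intercept a, so inverse targets
  with X\* > a raise the same error.
- **Silva** inversion solves a·u² + b·u + ln X\* = 0 in u = √t. Because
  ln X\* ≤ 0 the discriminant is ≥ b², and only the "+" root yields
  u ≥ 0; the other root is rejected by construction.
- **Rate singularities**: the Silva rate and the Page rate with b < 1
  diverge as t → 0⁺. `dimensionless_rate` requires t > 0 for those
  cases and raises a domain error naming the singularity; rate-curve
  sampling in the pipeline therefore starts at a configurable t_min
  (default 0.1 min).

## Fitting

Fitting happens in concentration space with X_eq held fixed: the
objective is Σᵢ[Xᵢ − X_eq(1 − f(tᵢ; a, b))]², minimised by
`scipy.optimize.least_squares` (trust-region reflective) with lower
bounds 10⁻¹⁰ on every parameter, ftol = xtol = gtol = 10⁻¹⁰, and at
most 10⁴ evaluations. An opt-in `free_x_eq` mode appends X_eq as a
third parameter for sensitivity analysis. There are no random
restarts: starting values come from deterministic linearisations using
only points with t > 0 and 0 < X\* < 1 —

- Lewis: through-the-origin slope of −ln X\* on t;
- Page: ordinary regression of ln(−ln X\*) on ln t;
- Peleg: the linear form t/(1 − X\*) = a + b·t;
- Henderson–Pabis: a = 1 with Lewis's rate as b;
- Silva: Lewis's rate as a with a small b (0.01).

χ² is reported as the **unweighted residual sum of squares** in
(mg/100 g)². Extraction kinetics studies rarely publish per-point
measurement variances, so the Bevington-style weighted statistic is
not computable by default; an optional per-point σ vector turns χ²
into Σ(rᵢ/σᵢ)² for users who have replicate uncertainties. R² is
1 − RSS/TSS about the observed mean, reported as NaN for constant
observations. Models are ranked by χ² ascending, ties broken by R²
descending and then by fewer parameters.

Degenerate inputs are rejected before optimisation: all-zero series,
series shorter than n_params + 2, non-increasing time grids.

## Derived quantities

- **Equilibrium**: arithmetic mean of the last `tail` observations of
  the fastest (near-plateau) condition. Default tail = 3 — a
  conventional choice for a 19-point schedule whose last three points
  span 110–130 min; a warning (not an error) is issued when the tail
  still trends upward by more than 5% of its mean.
- **Rate curves**: reported with a positive sign as
  dX/dt = −X_eq·df/dt, matching how extraction-rate figures are drawn;
  the signed dimensionless derivative remains available.
- **Process time**: the closed-form inverse at X\* = 1 − p for target
  fraction p (default 0.97). Report tables round to the nearest minute;
  raw values are retained in the JSON.
- **Percent extracted** at a comparison time (default 28 min):
  100·(1 − X\*(t)).

## Synthetic data

The generator emulates an orbital-shaker extraction experiment:
sampling on the dense-early schedule (0, 2, 4, 6, 8, 10, 15, 20, then
every 10 min from 30 to 130), a true empirical model driving the
noiseless curve, additive i.i.d. Gaussian measurement noise, and
truncation at zero (a spectrophotometric concentration reading cannot
be negative). The four-condition reference panel uses published Page
parameters for agitation at 0/50/100/150 rpm as ground truth with
shared X_eq = 13.1 mg/100 g.

The default noise σ = 0.3 mg/100 g is a calibration choice, not a
measured value: it puts refitted R² in the 0.98–0.997 band typical of
careful spectrophotometric kinetics. What the generator does **not**
emulate: replicate structure (single reading per time point),
heteroscedastic or autocorrelated errors, inter-batch variability, and
analyte degradation. Passing tests therefore demonstrate correctness of
the algebra and estimation pipeline under the stated noise model, not
robustness to every failure mode of real assay data.

A practical identifiability caveat the test suite respects: at
realistic noise the flexible two-parameter families are nearly
indistinguishable on a 19-point series — Page-generated data at
σ = 0.3 is won by the Silva model in roughly a third of seeds, since
e^(−at−b√t) closely mimics a stretched exponential (the same ambiguity
appears in real studies, where Silva can edge out Page at high
agitation). Model-recovery checks therefore either drop the noise to
σ = 0.05 (all five families) or restrict to non-nested competitors
(Lewis/Peleg/Page) at realistic noise.

## Numerical choices

- Round-trip (inverse∘forward) identity is verified to relative 10⁻⁸
  across models; analytic rates against central finite differences
  (step 10⁻⁴ min) to relative 10⁻⁵.
- Monte-Carlo checks use 100 seeded replicates; mean parameter recovery
  within 10% at σ = 0.2 mg/100 g. Replicate streams derive from
  `numpy.random.SeedSequence`, so panels with different master seeds
  are independent and identical seeds are bit-reproducible.
- The optimiser is deterministic end-to-end; pipeline reports contain
  no timestamps, and JSON is serialised with sorted keys, so identical
  config + seed yields byte-identical report files.
- The nearest-minute and one-decimal roundings in reports match how
  process times and percent-extracted values are conventionally quoted;
  raw doubles are always retained alongside.

## Limitations

- Single-temperature scope: temperature is carried as metadata only.
- χ² ranking without per-point variances cannot distinguish lack of
  fit from measurement noise; with ~19 points, two-parameter families
  often tie within noise (see above).
- The Peleg inverse is undefined at or below its asymptote; pipelines
  targeting high fractions (e.g. 0.97 ⇒ X\* = 0.03) will correctly
  raise for fitted b > 1/(1 − 0.03) ≈ 1.031.
- No confidence intervals on fitted parameters or derived times; the
  Monte-Carlo machinery in the synthetic module can be used for that,
  but it is not automated.
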