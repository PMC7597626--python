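# Methods

## Model

The package models a diurnal gas-exchange variable *p* (net assimilation,
stomatal conductance or transpiration) as a function of clock time alone.
The rate law assumes the change of *p* is proportional to *p* itself times a
time-decaying kernel truncated at second order:

    dp/dt = p · (ω/t + η/t²)

Separating variables and integrating gives the closed form

    p(t) = exp(ω·ln t − η/t + ψ)

where ψ absorbs the integration constant (the "opening value" of the series
at its first observation time). Only the products of the underlying
rate-law coefficients with the proportionality constant are identifiable, so
(ω, η, ψ) is the complete parameterization; higher-order 1/tⁿ terms (n > 2)
are a documented non-goal. The curve is singular at t = 0 and is evaluated
only for t > 0.

**Time axis.** t is decimal clock hours since local midnight (07:00 → 7.0).
This keeps every daytime measurement strictly positive and matches how field
instruments timestamp observations. Users who prefer a sunrise-relative
origin can pass `time_offset` to `fit_linearized`; the default is 0.

**Shape.** For ω < 0, η > 0 the curve rises, peaks at t\* = −η/ω and falls —
the canonical morning-peaking diurnal course. Other sign combinations are
monotone and are accepted by evaluation/fitting but rejected by
`peak_time`.

## Estimation

ln p is exactly linear in (ln t, −1/t, 1) with coefficients (ω, η, ψ), so
the estimator is ordinary least squares of ln(value) on that basis
(`numpy.linalg.lstsq`). Consequences the tests rely on:

- on noiseless model-generated data the fit is exact to machine precision;
- under multiplicative lognormal noise (errors proportional to signal, the
  natural error model for gas-exchange instruments) the log-scale residuals
  are Gaussian and OLS is the maximum-likelihood estimator.

Nonpositive observations cannot enter a log fit; they are excluded with a
warning rather than shifted — inventing an additive offset would change the
model. A cell needs ≥ 3 distinct usable times or it is reported as failed.

An optional `refine=True` pass polishes the estimate by Levenberg–Marquardt
least squares on the original scale, for users who want SSE minimized on
measurement units; it is off by default.

**Diagnostics.** The field convention reports *r* and *S* without defining
them precisely, so the package fixes: *r* = Pearson correlation of observed
vs fitted values on the original scale; *S* = √(SSE/(n−k)) on the original
scale with k = 3 fitted constants. A perfect fit gives r = 1, S = 0.
Replicates are pooled as individual points by default (`pool="points"`);
`pool="means"` fits per-hour replicate means instead — the two coincide on
noiseless data.

## Quadrature

The curve has no elementary antiderivative, so cumulative responses are
computed numerically: composite Simpson by default (trapezoid available),
target step 0.1 h, grid forced to an even interval count for Simpson. The
default window is the measurement day 07:00–17:00 — the fitted domain — and
windows must stay inside (0, 24) because of the t = 0 singularity; the
window, step and rule are all configurable. Integrals are reported in
response-unit × hours; no conversion to mol m⁻² day⁻¹ is attempted, and
running integrals are computed per grid prefix so they are exactly
consistent with the point-to-point quadrature. Amplitude shifts pass
through the integral exactly (adding δ to ψ multiplies every integral by
e^δ), which is what makes amplitude-only treatment effects carry a clean
interpretation on daily totals.

## Synthetic experiment

The generator emulates the factorial study the pipeline targets so every
stage is testable offline.

- **Design.** 4 soil-moisture bands (100–95, 80–75, 55–50, 35–30 % of field
  capacity) × 4 Si doses (0, 100, 300, 500 mg L⁻¹) × 5 replicates; three
  responses measured every 2 h, 07:00–17:00 (6 points).
- **Base curves.** All responses peak at 09:00 (ω = −5, η = 45, so
  t\* = 9). The shape scale is calibrated so ~60 % of the 07:00–17:00 total
  accumulates by noon — the reported front-loading of the day — giving a
  P_N course of roughly 25 → 30 → 13 µmol m⁻² s⁻¹. Peak amplitudes
  (P_N 30 µmol m⁻² s⁻¹, g_s 250 mmol m⁻² s⁻¹, E 4.5 mmol m⁻² s⁻¹) are
  order-of-magnitude realism for well-watered sugarcane, not reproductions
  of any measured leaf.
- **Treatment effects.** Pure amplitude scaling: ψ is shifted by
  ln(water × Si multiplier); ω, η untouched, so peak time is invariant
  across treatments. Water multipliers (1, 0.79, 0.60, 0.46) echo the
  ratios of reported daily-total ranges under increasing stress; Si
  multipliers (1, 1.03, 1.10, 1.06) echo the reported benefit ordering
  300 > 500 > 100 > 0 mg L⁻¹. Both are configuration, documented as
  calibration rather than ground truth.
- **Noise.** Multiplicative lognormal, σ_ln = 0.05 by default (≈5 % CV).
  Each factorial cell draws from its own seeded stream
  (`SeedSequence(seed, spawn_key=(band, dose))`), so tables are reproducible
  for a seed and independent of generation order.
- **Microclimate.** One deterministic cloudless reference day, built from
  monotone cubic (PCHIP) interpolants through anchor points, so anchors are
  reproduced exactly: RH 88 % at 06:00, minimum at 15:00, 36 % at 17:00;
  PPFD 0 at 05:00/19:00 with an 11:00–15:00 plateau (the plateau narrative
  was preferred over an alternative "9:00–13:00 peak" phrasing of the same
  day); Ta peaking 13:00–15:00 with sunset warmer than sunrise; Ca highest
  in early morning, lowest midday. VPD is derived from Ta and RH via the
  Tetens saturation-pressure approximation. PPFD/Ta/Ca magnitudes are
  invented defaults (no numeric axes were available); the anchor *shapes*
  are the contract.

**What passing tests do and do not show.** The generator realizes exactly
the model the estimator assumes (log-linear curve, lognormal noise,
amplitude-only treatment effects, no autocorrelation, no phase shifts, no
climate coupling). Recovery and ordering results on synthetic data
therefore validate the machinery — estimator correctness, quadrature
accuracy, pipeline plumbing — not the biological adequacy of a time-only
model for real leaves, where afternoon depression, weather and stomatal
patchiness produce structure this generator deliberately omits.

## Treatment comparison

Percent gain is 100·(treated − control)/control, computed by default on
fitted values at each measurement hour (mirroring per-hour gain reporting
against the in-band 0-Si control and against the well-watered band);
`gain_on="raw"` switches to replicate means of the raw data. The ANOVA
screen is a classical one-way F test across the four Si doses, run per
water band × response × hour at α = 0.05 with no multiplicity correction —
matching per-time-point screening practice — with an optional Holm
step-down (`holm=True`) across the six hours of a band × response family.
Identical replicates (zero within-group variance, as arises at σ = 0) make
F undefined and raise a clear error instead of returning infinity.

## Numerical choices and degenerate inputs

- OLS via SVD (`lstsq`); the 3×3 normal-equation solve is kept in the test
  suite as an independent oracle, not used in the implementation.
- Quadrature default step 0.1 h: polynomial closed forms are matched to
  1e−8 and halving the trapezoid step shrinks its error fourfold.
- `goodness_r` clips rounding excursions into [−1, 1]; zero-variance input
  is an error, not NaN.
- Domain errors (t ≤ 0, empty windows, cutoffs outside the window, unknown
  bands/doses, malformed measurement CSVs) raise `ValueError` naming the
  offending quantity — and, for CSV input, the offending row.
- Report CSVs are written with a fixed float format so identical
  configurations and seeds produce byte-identical bundles.

## Problem sizes

Default analyses run the full 4 × 4 × 5 × 6 × 3 experiment (1 440
measurements, 48 fitted cells) in well under a second; Monte-Carlo checks
use 500 refits of a 30-point design. These sizes were chosen to match the
emulated study design, which is small by construction.

## Known limitations

- The model is time-only: no PPFD, temperature or VPD covariates, no
  mechanistic photosynthesis (FvCB) structure.
- Parameter uncertainty (confidence intervals on ω, η, ψ) is not reported.
- Daily totals are in response-unit × hours; published totals printed in
  instantaneous units cannot be reproduced without the original fitted
  constants and an explicit window convention.
- The ANOVA screen treats hours independently; repeated-measures or
  mixed-effects structure is out of scope.
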