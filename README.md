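# diurnalfit

Modelling of the within-day time course of leaf gas exchange — net CO₂
assimilation (*P*ₙ), stomatal conductance (*g*ₛ) and transpiration (*E*) — for
plant ecophysiologists studying how water stress and silicon nutrition shape
diurnal photosynthetic performance (the motivating system is sugarcane under
four soil-moisture regimes crossed with four Si doses).

## The model

Gas-exchange variables rise after sunrise, peak mid-morning and decline to an
evening minimum. `diurnalfit` describes this with a time-only rate law in
which the relative rate of change decays with clock time *t* (hours since
midnight):

    dp/dt = p · (ω/t + η/t²)

whose solution is the log-linear curve

    p(t) = exp(ω·ln t − η/t + ψ),   t > 0.

With ω < 0 and η > 0 the curve is unimodal with its peak at **t\* = −η/ω**;
ψ sets the amplitude on the log scale. The curve is singular at t = 0, so all
evaluation requires t > 0 (daytime measurements start at 07:00).

Because ln p is exactly linear in (ln t, −1/t, 1), the constants are fitted
by ordinary least squares on the log scale — closed-form and deterministic.
Fit quality is reported as the Pearson correlation *r* between observed and
back-transformed fitted values and the residual standard error
S = √(SSE/(n−3)), both on the original measurement scale. Daily totals and
the share of the day's response achieved by any cutoff hour come from
composite Simpson quadrature of the fitted curve (the integral has no
elementary closed form).

A synthetic-experiment module generates the full factorial design — water
bands 100–95, 80–75, 55–50, 35–30 %FC × Si doses 0, 100, 300, 500 mg L⁻¹ ×
5 replicates, measured every 2 h from 07:00 to 17:00 — with multiplicative
lognormal noise, plus a cloudless-day microclimate (PPFD, Ta, RH, Ca, VPD)
pinned to observed anchors (RH 88 % at 06:00 falling to 36 % at 17:00, PPFD
zero at 05:00 and 19:00). Treatments scale curve amplitude only, so every
cell shares the 09:00 peak.

## Worked example

```python
import numpy as np
from diurnalfit import (DiurnalSeries, ModelParams, evaluate_response,
                        fit_linearized, daily_total, fraction_achieved_by)

rng = np.random.default_rng(0)
truth = ModelParams(omega=-5.0, eta=45.0, psi=19.39)       # peak at 9:00
times = np.array([7.0, 9.0, 11.0, 13.0, 15.0, 17.0])
values = evaluate_response(truth, times) * np.exp(rng.normal(0, 0.05, 6))

fit = fit_linearized(DiurnalSeries("PN", times, values))
print(fit.params, fit.r, fit.S)
print(daily_total(fit.params, window=(7, 17)))
print(fraction_achieved_by(fit.params, 12.0, window=(7, 17)))
```

prints (run `python examples/01_fit_diurnal_curve.py` and
`02_cumulative_totals.py` for the annotated versions):

```
fitted constants: omega=-5.046 eta=45.441 psi=19.547
goodness of fit:  r=0.9977  S=0.5721 on n=6 points
daily total over 07:00-17:00: 234.15 (response-units x hours)
fraction achieved by noon:    60.3%
```

The fit recovers the generating constants to a few percent from six noisy
points; the 09:00-peaking curve banks ~60 % of the day's assimilation before
noon. `examples/03_simulate_experiment.py` and `04_treatment_report.py` run
the factorial simulation and the full report (constants, cumulative totals,
percent gains vs the 0-Si control, per-hour one-way ANOVA across Si doses).

The same stages are available from the shell:

```sh
diurnalfit simulate --seed 1 --out-dir run1
diurnalfit fit run1/measurements.csv --out run1/constants.csv
diurnalfit report --seed 1 --out-dir run1/report
```

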