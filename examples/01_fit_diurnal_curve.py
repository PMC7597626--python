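"""Fit the log-linear diurnal curve to one morning-peaking gas-exchange series.

Builds a six-point net-assimilation series (every 2 h, 07:00-17:00) with 5%
multiplicative noise around a known curve, fits it, and prints the estimated
constants with the goodness-of-fit statistics.
"""

import numpy as np

from diurnalfit import DiurnalSeries, ModelParams, evaluate_response, fit_linearized, peak_time

rng = np.random.default_rng(0)
truth = ModelParams(omega=-5.0, eta=45.0, psi=19.39)  # peaks at t* = -eta/omega = 9.0

times = np.array([7.0, 9.0, 11.0, 13.0, 15.0, 17.0])
values = evaluate_response(truth, times) * np.exp(rng.normal(0, 0.05, times.size))

fit = fit_linearized(DiurnalSeries("PN", times, values))

print("true constants:   omega=%.3f eta=%.3f psi=%.3f" % (truth.omega, truth.eta, truth.psi))
print(
    "fitted constants: omega=%.3f eta=%.3f psi=%.3f"
    % (fit.params.omega, fit.params.eta, fit.params.psi)
)
print("fitted peak time: %.2f h (true 9.00 h)" % peak_time(fit.params))
print("goodness of fit:  r=%.4f  S=%.4f on n=%d points" % (fit.r, fit.S, fit.n))
print()
print("r is the observed-vs-fitted Pearson correlation and S the residual")
print("standard error, both on the original measurement scale; r near 1 and")
print("S well below the signal amplitude mean the curve explains the series.")
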