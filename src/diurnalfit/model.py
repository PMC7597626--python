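"""Closed-form diurnal response curve and its rate law.

The model treats the within-day time course of a leaf gas-exchange variable
``p`` (net assimilation, stomatal conductance or transpiration) as driven by
its own magnitude with a rate that decays in time::

    dp/dt = p * (omega/t + eta/t**2)

whose solution on ``t > 0`` is the log-linear curve::

    p(t) = exp(omega * ln(t) - eta/t + psi)

``t`` is decimal clock hours since local midnight (07:00 -> 7.0), which keeps
every daytime measurement strictly positive; the curve has a singularity at
``t = 0`` and is not defined there.  With ``omega < 0`` and ``eta > 0`` the
curve rises from dawn, peaks at ``t* = -eta/omega`` and declines toward
evening -- the unimodal shape of a diurnal photosynthesis series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "evaluate_response", "response_rate", "peak_time"]


@dataclass(frozen=True)
class ModelParams:
    """Constants of the diurnal curve ``p(t) = exp(omega*ln t - eta/t + psi)``.

    Parameters
    ----------
    omega : float
        Dimensionless coefficient of ``ln t``.  Negative for a curve that
        falls off in the afternoon.
    eta : float
        Coefficient of ``1/t`` (hours).  Positive for a curve suppressed
        near dawn.
    psi : float
        Dimensionless log-scale intercept; ``exp(psi)`` sets the overall
        amplitude in the units of the fitted response.

    Only the products of the underlying rate-law constants with the
    proportionality constant are identifiable, so the three fields above are
    the complete parameterization.  Higher-order ``1/t**n`` terms (n > 2) of
    the general rate law are deliberately not represented.
    """

    omega: float
    eta: float
    psi: float

    def __post_init__(self) -> None:
        for name in ("omega", "eta", "psi"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"ModelParams.{name} must be finite, got {v!r}")

    @property
    def is_unimodal(self) -> bool:
        """True when the curve rises then falls on ``t > 0`` (omega<0, eta>0)."""
        return self.omega < 0 and self.eta > 0

    def require_unimodal(self) -> None:
        if not self.is_unimodal:
            raise ValueError(
                "diurnal-unimodal shape requires omega < 0 and eta > 0; "
                f"got omega={self.omega}, eta={self.eta}"
            )

    def shifted_amplitude(self, log_factor: float) -> "ModelParams":
        """Return a copy with ``psi`` shifted by ``log_factor``.

        Multiplies the whole curve by ``exp(log_factor)`` while leaving the
        peak time untouched.
        """
        return ModelParams(self.omega, self.eta, self.psi + float(log_factor))


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError(
            "response curve exp(omega*ln t - eta/t + psi) is singular at t = 0 "
            "and undefined for t <= 0; pass decimal clock hours > 0"
        )
    return t


def evaluate_response(params: ModelParams, t) -> np.ndarray | float:
    """Evaluate ``p(t) = exp(omega*ln t - eta/t + psi)`` at clock hour(s) ``t``.

    Accepts a scalar or array of decimal hours; returns the same shape.
    The result is strictly positive for every finite parameter set.
    """
    tt = _check_time(t)
    out = np.exp(params.omega * np.log(tt) - params.eta / tt + params.psi)
    return out if out.ndim else float(out)


def response_rate(params: ModelParams, t) -> np.ndarray | float:
    """The model rate ``dp/dt = p(t) * (omega/t + eta/t**2)`` (units/hour)."""
    tt = _check_time(t)
    p = np.exp(params.omega * np.log(tt) - params.eta / tt + params.psi)
    out = p * (params.omega / tt + params.eta / tt**2)
    return out if out.ndim else float(out)


def peak_time(params: ModelParams) -> float:
    """Clock hour of the curve's interior maximum, ``t* = -eta/omega``.

    Only defined for the unimodal sign pattern (omega < 0, eta > 0); the
    rate vanishes where ``omega/t = -eta/t**2``.
    """
    if not params.is_unimodal:
        raise ValueError(
            "no interior peak: need omega < 0 and eta > 0, "
            f"got omega={params.omega}, eta={params.eta}"
        )
    return -params.eta / params.omega
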