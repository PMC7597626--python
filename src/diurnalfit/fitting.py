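"""Estimate diurnal-curve constants from observed gas-exchange series.

Because ``ln p = omega*ln t - eta/t + psi`` is exactly linear in
``(ln t, -1/t, 1)``, the constants are estimated by ordinary least squares on
the log scale -- closed form, deterministic, no starting values.  Fit quality
is reported the way field studies summarize it: the Pearson correlation ``r``
between observed and back-transformed fitted values and the residual standard
error ``S`` (sqrt(SSE/(n-k))), both on the original response scale.

An optional Gauss-Newton style refinement minimizing the original-scale SSE
is available behind the ``refine`` flag; it is off by default because the
log-scale estimator is exact on noiseless data and unbiased under the
multiplicative error model the measurements follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import ModelParams, evaluate_response

__all__ = [
    "DiurnalSeries",
    "FitResult",
    "goodness_r",
    "goodness_S",
    "fit_linearized",
    "fit_all",
    "RESPONSE_UNITS",
]

#: Canonical response kinds and their measurement units.
RESPONSE_UNITS = {
    "PN": "umol CO2 m-2 s-1",
    "GS": "mmol H2O m-2 s-1",
    "E": "mmol H2O m-2 s-1",
}


@dataclass(frozen=True)
class DiurnalSeries:
    """One diurnal series of a single response under one treatment.

    ``t`` holds decimal clock hours (> 0), ``value`` the measured response;
    replicate measurements at the same hour simply repeat the time.
    """

    response_kind: str
    t: np.ndarray
    value: np.ndarray
    water_band: str | None = None
    si_dose: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have equal length")
        if np.any(self.t <= 0):
            raise ValueError("all observation times must be > 0 (clock hours)")


@dataclass(frozen=True)
class FitResult:
    """Fitted constants plus diagnostics for one diurnal series."""

    params: ModelParams
    n: int
    r: float
    S: float
    window: tuple[float, float]
    time_offset: float = 0.0

    def predict(self, t) -> np.ndarray | float:
        return evaluate_response(self.params, np.asarray(t, dtype=float) - self.time_offset)


def goodness_r(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson product-moment correlation between observed and fitted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equally sized sequences of length >= 2")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("correlation undefined: zero variance in a sequence")
    obs_c = obs - obs.mean()
    pred_c = pred - pred.mean()
    r = float(obs_c @ pred_c / np.sqrt((obs_c @ obs_c) * (pred_c @ pred_c)))
    return min(1.0, max(-1.0, r))


def goodness_S(observed: Sequence[float], predicted: Sequence[float], k: int = 3) -> float:
    """Residual standard error sqrt(SSE / (n - k)); k defaults to the 3 constants."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n <= k:
        raise ValueError(f"no residual degrees of freedom: n={n} <= k={k}")
    sse = float(np.sum((obs - pred) ** 2))
    return float(np.sqrt(sse / (n - k)))


def _design_matrix(t: np.ndarray) -> np.ndarray:
    # ln p = omega*ln(t) + eta*(-1/t) + psi
    return np.column_stack([np.log(t), -1.0 / t, np.ones_like(t)])


def fit_linearized(
    series: DiurnalSeries,
    *,
    refine: bool = False,
    time_offset: float = 0.0,
) -> FitResult:
    """Fit (omega, eta, psi) to one series by OLS of ``ln(value)`` on the predictors.

    Nonpositive observations cannot enter the log fit and are excluded with a
    warning (never shifted).  ``time_offset`` subtracts a constant from all
    clock times before fitting, for users who prefer a sunrise-based origin;
    the default keeps clock hours since midnight.

    Raises
    ------
    ValueError
        Fewer than 3 distinct usable times, or a singular (all-equal-time)
        design.
    """
    t = series.t - time_offset
    if np.any(t <= 0):
        raise ValueError("time_offset leaves nonpositive times; model undefined there")
    y = series.value

    keep = y > 0
    if not np.all(keep):
        warnings.warn(
            f"excluded {int((~keep).sum())} nonpositive value(s) from the log-scale fit",
            UserWarning,
            stacklevel=2,
        )
    t, y = t[keep], y[keep]
    if np.unique(t).size < 3:
        raise ValueError(
            f"insufficient data: need >= 3 distinct positive-time points, have {np.unique(t).size}"
        )

    X = _design_matrix(t)
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    params = ModelParams(*map(float, beta))

    if refine:
        params = _refine_original_scale(params, t, y)

    pred = evaluate_response(params, t)
    return FitResult(
        params=params,
        n=int(t.size),
        r=goodness_r(y, pred),
        S=goodness_S(y, pred, k=3),
        window=(float(t.min() + time_offset), float(t.max() + time_offset)),
        time_offset=float(time_offset),
    )


def _refine_original_scale(start: ModelParams, t: np.ndarray, y: np.ndarray) -> ModelParams:
    """Polish the log-scale estimate by least squares on the original scale."""

    def resid(beta):
        return evaluate_response(ModelParams(*beta), t) - y

    sol = least_squares(resid, x0=[start.omega, start.eta, start.psi], method="lm")
    return ModelParams(*map(float, sol.x))


@dataclass
class FitTable:
    """Per-cell fit results of a factorial experiment, plus failed cells."""

    constants: pd.DataFrame
    failures: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.constants.to_csv(path, index=False)


_CONSTANTS_COLUMNS = [
    "water_band",
    "si_dose_mg_per_L",
    "response_kind",
    "omega",
    "eta",
    "psi",
    "n",
    "r",
    "S",
]


def fit_all(
    table: pd.DataFrame,
    kinds: Iterable[str] = ("PN", "GS", "E"),
    *,
    refine: bool = False,
    pool: str = "points",
) -> FitTable:
    """Fit every water-band x Si-dose x response-kind cell of a measurement table.

    ``table`` is a long-format measurement frame (columns ``water_band``,
    ``si_dose_mg_per_L``, ``replicate``, ``time_h``, ``response_kind``,
    ``value``).  Replicates are pooled as individual points (``pool="points"``)
    or averaged per time before fitting (``pool="means"``).

    Cells whose series cannot be fitted are reported in ``FitTable.failures``
    with the reason, never silently dropped.
    """
    if table.empty:
        raise ValueError("empty measurement table")
    if pool not in ("points", "means"):
        raise ValueError(f"pool must be 'points' or 'means', got {pool!r}")

    kinds = set(kinds)
    rows, fails = [], []
    grouped = table[table["response_kind"].isin(kinds)].groupby(
        ["water_band", "si_dose_mg_per_L", "response_kind"], sort=True
    )
    for (band, dose, kind), cell in grouped:
        t = cell["time_h"].to_numpy(dtype=float)
        v = cell["value"].to_numpy(dtype=float)
        if pool == "means":
            m = cell.groupby("time_h")["value"].mean()
            t, v = m.index.to_numpy(dtype=float), m.to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                fit = fit_linearized(
                    DiurnalSeries(kind, t, v, water_band=band, si_dose=dose),
                    refine=refine,
                )
        except ValueError as exc:
            fails.append(
                {
                    "water_band": band,
                    "si_dose_mg_per_L": dose,
                    "response_kind": kind,
                    "reason": str(exc),
                }
            )
            continue
        rows.append(
            {
                "water_band": band,
                "si_dose_mg_per_L": dose,
                "response_kind": kind,
                "omega": fit.params.omega,
                "eta": fit.params.eta,
                "psi": fit.params.psi,
                "n": fit.n,
                "r": fit.r,
                "S": fit.S,
            }
        )
    return FitTable(
        constants=pd.DataFrame(rows, columns=_CONSTANTS_COLUMNS),
        failures=pd.DataFrame(fails, columns=["water_band", "si_dose_mg_per_L", "response_kind", "reason"]),
    )
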