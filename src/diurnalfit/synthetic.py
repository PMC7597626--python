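"""Synthetic drought x silicon factorial experiment and diurnal microclimate.

Emulates the study design the pipeline targets: sugarcane plants grown in
four soil-moisture bands (100-95, 80-75, 55-50, 35-30 % of field capacity)
crossed with four silicon doses (0, 100, 300, 500 mg/L), five replicate
plants, gas exchange (net assimilation PN, stomatal conductance GS,
transpiration E) measured every 2 h from 07:00 to 17:00 on a cloudless day.

Every cell's true diurnal curve is the log-linear model with an
amplitude multiplier per treatment: water stress scales the whole curve down,
silicon scales it up, and neither moves the 09:00 peak (treatment effects in
the source system shift amplitude, not phase).  Measurement error is
multiplicative lognormal -- gas-exchange noise scales with signal and stays
positive, which also keeps the log-scale fit well defined.

Default multipliers are calibration, not ground truth: the water factors
(1, 0.79, 0.60, 0.46) echo the ratios of reported daily-total ranges under
mild/moderate/severe stress, and the silicon factors (1, 1.03, 1.10, 1.06)
echo the reported gain ordering 300 > 500 > 100 > 0 mg/L.

A companion generator produces the day's microclimate (PPFD, air temperature,
relative humidity, CO2 concentration, VPD) as smooth curves pinned to the
observed anchors: PPFD zero at 05:00 and 19:00 with an 11:00-15:00 plateau,
RH 88% at 06:00 falling to a 15:00 minimum then 36% at 17:00, temperature
peaking 13:00-15:00 with sunset warmer than sunrise, CO2 highest in early
morning and lowest midday.  Axis magnitudes not stated in the narrative
(PPFD, Ta, Ca levels) are invented, order-of-magnitude defaults.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

from .model import ModelParams, evaluate_response
from .fitting import RESPONSE_UNITS

__all__ = [
    "WATER_BANDS",
    "SI_DOSES",
    "TreatmentDesign",
    "SyntheticConfig",
    "ClimateProfile",
    "params_with_peak",
    "generate_climate",
    "vpd_from",
    "true_params_for",
    "generate_gas_exchange",
    "generate_experiment",
]

#: Soil-moisture bands, % of field capacity, wettest (control) first.
WATER_BANDS = ("100-95", "80-75", "55-50", "35-30")
#: Silicon doses, mg per litre.
SI_DOSES = (0, 100, 300, 500)
#: Gas-exchange sampling hours (every 2 h, 07:00-17:00).
DEFAULT_SAMPLE_TIMES = (7.0, 9.0, 11.0, 13.0, 15.0, 17.0)


def params_with_peak(omega: float, eta: float, peak_value: float) -> ModelParams:
    """Build unimodal ModelParams whose maximum equals ``peak_value``.

    Solves for psi given the peak at t* = -eta/omega.
    """
    p = ModelParams(omega, eta, 0.0)
    p.require_unimodal()
    t_star = -eta / omega
    psi = math.log(peak_value) - (omega * math.log(t_star) - eta / t_star)
    return ModelParams(omega, eta, psi)


@dataclass(frozen=True)
class TreatmentDesign:
    """One factorial cell: a soil-moisture band and a silicon dose."""

    water_band: str
    si_dose: int
    replicates: int = 5
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES

    def __post_init__(self):
        if self.water_band not in WATER_BANDS:
            raise ValueError(f"unknown water band {self.water_band!r}; expected one of {WATER_BANDS}")
        if self.si_dose not in SI_DOSES:
            raise ValueError(f"unknown Si dose {self.si_dose!r}; expected one of {SI_DOSES}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        st = np.asarray(self.sample_times, dtype=float)
        if np.any(st <= 0) or np.any(np.diff(st) <= 0):
            raise ValueError("sample_times must be strictly increasing and > 0")


def _default_base_params() -> dict[str, ModelParams]:
    # All three responses peak at 09:00 (-eta/omega = 9); amplitudes are
    # order-of-magnitude realistic for well-watered sugarcane leaves.  The
    # shape scale (omega=-5, eta=45) is calibrated so ~60% of the 07-17 h
    # total accumulates by noon, with a strong decline to the 17:00 minimum.
    return {
        "PN": params_with_peak(-5.0, 45.0, 30.0),   # umol CO2 m-2 s-1
        "GS": params_with_peak(-5.0, 45.0, 250.0),  # mmol H2O m-2 s-1
        "E": params_with_peak(-5.0, 45.0, 4.5),     # mmol H2O m-2 s-1
    }


@dataclass
class SyntheticConfig:
    """Generator settings: seed, noise level, base curves, treatment multipliers."""

    seed: int = 0
    noise_sigma_ln: float = 0.05
    base_params: dict[str, ModelParams] = field(default_factory=_default_base_params)
    water_multipliers: dict[str, float] = field(
        default_factory=lambda: {"100-95": 1.0, "80-75": 0.79, "55-50": 0.60, "35-30": 0.46}
    )
    si_multipliers: dict[int, float] = field(
        default_factory=lambda: {0: 1.0, 100: 1.03, 300: 1.10, 500: 1.06}
    )

    def __post_init__(self):
        if self.noise_sigma_ln < 0:
            raise ValueError("noise_sigma_ln must be >= 0")
        wm = self.water_multipliers
        if wm[WATER_BANDS[0]] != 1.0:
            raise ValueError("control water band must have multiplier 1")
        ordered = [wm[b] for b in WATER_BANDS]
        if not all(a > b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("water multipliers must strictly decrease with stress severity")
        sm = self.si_multipliers
        if sm[0] != 1.0:
            raise ValueError("0-dose silicon multiplier must be 1")
        if not (sm[300] > sm[500] > sm[100] > sm[0]):
            raise ValueError("silicon multipliers must be ordered 300 > 500 > 100 > 0 mg/L")

    # --- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_params"] = {k: vars(p) for k, p in self.base_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "base_params" in d:
            d["base_params"] = {k: ModelParams(**v) for k, v in d["base_params"].items()}
        if "si_multipliers" in d:
            d["si_multipliers"] = {int(k): float(v) for k, v in d["si_multipliers"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# Microclimate
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClimateProfile:
    """Diurnal microclimate series for the measurement day."""

    times: np.ndarray          # decimal hours
    ppfd: np.ndarray           # umol m-2 s-1
    ta: np.ndarray             # deg C
    rh: np.ndarray             # %
    ca: np.ndarray             # umol mol-1
    vpd: np.ndarray            # kPa

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "ppfd_umol_m2_s": self.ppfd,
                "ta_C": self.ta,
                "rh_pct": self.rh,
                "ca_umol_mol": self.ca,
                "vpd_kPa": self.vpd,
            }
        )


def vpd_from(ta, rh):
    """Vapor pressure deficit (kPa) from air temperature (C) and RH (%).

    Saturation vapor pressure by the Tetens approximation,
    ``es = 0.61078 * exp(17.27*Ta / (Ta + 237.3))``, times ``(1 - RH/100)``.
    """
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must lie in [0, 100] %")
    es = 0.61078 * np.exp(17.27 * ta / (ta + 237.3))
    out = es * (1.0 - rh / 100.0)
    return out if out.ndim else float(out)


# Anchor tables for the monotone-interpolated climate curves.  RH anchors at
# 06:00 (88%), minimum at 15:00 and 36% at 17:00 are observed values; PPFD is
# pinned to zero at 05:00/19:00 with a plateau 11:00-15:00; the remaining
# magnitudes are invented defaults.
_CLIMATE_ANCHORS = {
    "ppfd": [(5, 0.0), (7, 650.0), (9, 1350.0), (11, 1800.0), (13, 1800.0),
             (15, 1800.0), (17, 850.0), (19, 0.0)],
    "ta": [(5, 22.0), (7, 25.0), (9, 29.0), (11, 32.0), (13, 34.0),
           (15, 34.0), (17, 31.5), (19, 28.0)],
    "rh": [(5, 92.0), (6, 88.0), (9, 68.0), (12, 46.0), (15, 30.0),
           (17, 36.0), (19, 48.0)],
    "ca": [(5, 420.0), (7, 412.0), (9, 396.0), (11, 385.0), (13, 380.0),
           (15, 381.0), (17, 394.0), (19, 408.0)],
}


def generate_climate(
    config: SyntheticConfig | None = None,
    times: Sequence[float] | None = None,
) -> ClimateProfile:
    """Generate the measurement-day microclimate on ``times`` (default 05:00-19:00 each 0.5 h).

    Curves are monotone cubic (PCHIP) interpolants through the anchor points,
    so every anchor value is reproduced exactly and the curves are monotone
    between anchors (RH decreasing 06:00-15:00, increasing 15:00-17:00).
    VPD is derived from Ta and RH by :func:`vpd_from`.  The profile is
    deterministic -- one cloudless reference day, not a weather simulation.
    """
    t = np.asarray(times if times is not None else np.arange(5.0, 19.0 + 1e-9, 0.5), dtype=float)
    if np.any(t < 5.0) or np.any(t > 19.0):
        raise ValueError("climate profile is defined for 05:00-19:00")

    series = {}
    for name, anchors in _CLIMATE_ANCHORS.items():
        xs, ys = map(np.asarray, zip(*anchors))
        series[name] = PchipInterpolator(xs, ys)(t)
    series["ppfd"] = np.clip(series["ppfd"], 0.0, None)
    series["rh"] = np.clip(series["rh"], 0.0, 100.0)
    return ClimateProfile(
        times=t,
        ppfd=series["ppfd"],
        ta=series["ta"],
        rh=series["rh"],
        ca=series["ca"],
        vpd=vpd_from(series["ta"], series["rh"]),
    )


# --------------------------------------------------------------------------
# Gas-exchange generator
# --------------------------------------------------------------------------

def true_params_for(design: TreatmentDesign, config: SyntheticConfig, kind: str) -> ModelParams:
    """True curve constants for one treatment cell and response kind.

    Treatment effects enter as a pure amplitude factor: psi is shifted by
    ``ln(water_multiplier * si_multiplier)`` while omega and eta stay fixed,
    so the 09:00 peak time is identical across all treatments.
    """
    if kind not in config.base_params:
        raise ValueError(f"unknown response kind {kind!r}")
    wm = config.water_multipliers[design.water_band]
    sm = config.si_multipliers[design.si_dose]
    return config.base_params[kind].shifted_amplitude(math.log(wm * sm))


def _cell_rng(config: SyntheticConfig, design: TreatmentDesign) -> np.random.Generator:
    # Per-cell stream: deterministic for a given seed and independent of the
    # order in which cells are generated.
    band_i = WATER_BANDS.index(design.water_band)
    dose_i = SI_DOSES.index(design.si_dose)
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(band_i, dose_i)))


def generate_gas_exchange(design: TreatmentDesign, config: SyntheticConfig) -> pd.DataFrame:
    """Noisy measurement table for one factorial cell.

    For every replicate x sample time x response kind the value is
    ``true_curve(t) * exp(eps)`` with ``eps ~ Normal(0, noise_sigma_ln^2)``;
    deterministic given ``config.seed``.
    """
    rng = _cell_rng(config, design)
    times = np.asarray(design.sample_times, dtype=float)
    rows = []
    for kind in sorted(config.base_params):
        params = true_params_for(design, config, kind)
        clean = evaluate_response(params, times)
        for rep in range(1, design.replicates + 1):
            eps = rng.normal(0.0, config.noise_sigma_ln, size=times.size)
            values = clean * np.exp(eps)
            for t, v in zip(times, values):
                rows.append(
                    {
                        "water_band": design.water_band,
                        "si_dose_mg_per_L": design.si_dose,
                        "replicate": rep,
                        "time_h": t,
                        "response_kind": kind,
                        "value": v,
                        "units": RESPONSE_UNITS[kind],
                    }
                )
    return pd.DataFrame(rows)


def generate_experiment(
    config: SyntheticConfig,
    replicates: int = 5,
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
) -> pd.DataFrame:
    """Full 4 x 4 factorial measurement table (all bands x doses x kinds)."""
    frames = [
        generate_gas_exchange(
            TreatmentDesign(band, dose, replicates=replicates, sample_times=tuple(sample_times)),
            config,
        )
        for band in WATER_BANDS
        for dose in SI_DOSES
    ]
    return pd.concat(frames, ignore_index=True)
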