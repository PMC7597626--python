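"""End-to-end orchestration: measurements in, report tables out.

The pipeline ties the stages together for a whole factorial experiment:

1. read (or simulate) a long-format measurement table,
2. fit the diurnal curve per water-band x Si-dose x response cell,
3. integrate each fitted curve for cumulative totals and fraction-by-noon,
4. compare treatments -- percent gain against the 0-Si control within each
   water band and against the well-watered band, and a one-way ANOVA across
   Si doses at every measurement hour,
5. write everything as CSV plus a run manifest.

All outputs are deterministic for a given configuration and seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitTable, fit_all
from .integrate import DEFAULT_RULE, DEFAULT_STEP, DEFAULT_WINDOW, cumulative_curve, fraction_achieved_by
from .model import ModelParams, evaluate_response
from .synthetic import SI_DOSES, WATER_BANDS, SyntheticConfig, generate_climate, generate_experiment

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "percent_gain",
    "anova_oneway",
    "RunConfig",
    "ReportBundle",
    "run_pipeline",
]

logger = logging.getLogger("diurnalfit")

#: Mandatory header of a measurement CSV, in order.
MEASUREMENT_COLUMNS = [
    "water_band",
    "si_dose_mg_per_L",
    "replicate",
    "time_h",
    "response_kind",
    "value",
    "units",
]


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV.

    The header must contain exactly the columns of :data:`MEASUREMENT_COLUMNS`.
    Errors name the offending row (1-based, header excluded) so a bad record
    in a 480-row field file can be found quickly.
    """
    table = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header must be {MEASUREMENT_COLUMNS}")
    extra = [c for c in table.columns if c not in MEASUREMENT_COLUMNS]
    if extra:
        raise ValueError(f"{path}: unexpected column(s) {extra}")

    for col in ("si_dose_mg_per_L", "time_h", "value"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[numeric.isna() & table[col].notna()]
        if len(bad):
            row = int(bad[0]) + 1
            raise ValueError(f"{path} row {row}: unparseable number in column {col!r}: {table[col][bad[0]]!r}")
        if numeric.isna().any():
            row = int(table.index[numeric.isna()][0]) + 1
            raise ValueError(f"{path} row {row}: missing value in column {col!r}")
        table[col] = numeric

    nonpos = table.index[table["time_h"] <= 0]
    if len(nonpos):
        row = int(nonpos[0]) + 1
        raise ValueError(f"{path} row {row}: time_h must be > 0 (clock hours), got {table['time_h'][nonpos[0]]}")

    dup = table.duplicated(subset=["water_band", "si_dose_mg_per_L", "replicate", "time_h", "response_kind"])
    if dup.any():
        row = int(table.index[dup][0]) + 1
        raise ValueError(f"{path} row {row}: duplicate replicate record within a treatment cell")
    return table[MEASUREMENT_COLUMNS]


def write_measurements(table: pd.DataFrame, path) -> None:
    """Write a measurement table with the canonical header."""
    table[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def percent_gain(treated, control):
    """Percentage gain of a treated value against its control: 100*(T-C)/C.

    Losses come out negative.  Undefined for a zero control.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if np.any(control == 0):
        raise ValueError("percent gain undefined for a zero control value")
    out = 100.0 * (treated - control) / control
    return out if out.ndim else float(out)


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: between/within mean-square ratio F and its p-value.

    Requires at least two groups of at least two values each and positive
    pooled within-group variance (identical replicates give an undefined F).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 values")
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    if ssw == 0.0:
        raise ValueError("degenerate groups: zero within-group variance, F undefined")
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: a measurement CSV (``input_csv``) or a
    synthetic experiment (``synthetic``).  The window/step/rule control the
    quadrature stage; ``alpha`` is the per-time ANOVA significance level and
    ``holm`` switches on a Holm step-down correction across the time points
    of each band x response (off by default, matching per-time testing).
    """

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    out_dir: str = "report"
    window: tuple[float, float] = DEFAULT_WINDOW
    step: float = DEFAULT_STEP
    rule: str = DEFAULT_RULE
    noon: float = 12.0
    alpha: float = 0.05
    holm: bool = False
    gain_on: str = "fitted"  # or "raw"

    def __post_init__(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("configure exactly one of input_csv or synthetic")
        if self.gain_on not in ("fitted", "raw"):
            raise ValueError("gain_on must be 'fitted' or 'raw'")


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run, mirroring the CSVs on disk."""

    measurements: pd.DataFrame
    constants: pd.DataFrame
    failures: pd.DataFrame
    cumulative: pd.DataFrame
    gains: pd.DataFrame
    anova: pd.DataFrame
    manifest: dict
    climate: pd.DataFrame | None = None


def _cumulative_table(constants: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    t0, t1 = cfg.window
    grid = np.arange(t0, t1 + 1e-9, 1.0)
    for rec in constants.itertuples(index=False):
        params = ModelParams(rec.omega, rec.eta, rec.psi)
        cum = cumulative_curve(params, grid, step=cfg.step, rule=cfg.rule)
        frac_noon = fraction_achieved_by(params, cfg.noon, window=cfg.window, step=cfg.step, rule=cfg.rule)
        for t, c in zip(cum.grid, cum.cumulative):
            rows.append(
                {
                    "water_band": rec.water_band,
                    "si_dose_mg_per_L": rec.si_dose_mg_per_L,
                    "response_kind": rec.response_kind,
                    "t": t,
                    "cumulative": c,
                    "daily_total": cum.daily_total,
                    "fraction_by_noon": frac_noon,
                }
            )
    return pd.DataFrame(rows)


def _gain_table(constants: pd.DataFrame, measurements: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Percent gains per measurement hour: vs the 0-Si dose within each band
    and vs the well-watered control band at the same dose."""
    times = np.sort(measurements["time_h"].unique())

    def values_for(band, dose, kind):
        if cfg.gain_on == "fitted":
            row = constants.query(
                "water_band == @band and si_dose_mg_per_L == @dose and response_kind == @kind"
            )
            if row.empty:
                return None
            r = row.iloc[0]
            return evaluate_response(ModelParams(r.omega, r.eta, r.psi), times)
        cell = measurements.query(
            "water_band == @band and si_dose_mg_per_L == @dose and response_kind == @kind"
        )
        if cell.empty:
            return None
        m = cell.groupby("time_h")["value"].mean()
        return m.reindex(times).to_numpy()

    control_band = WATER_BANDS[0]
    rows = []
    kinds = sorted(constants["response_kind"].unique())
    bands = [b for b in WATER_BANDS if b in set(constants["water_band"])]
    doses = sorted(constants["si_dose_mg_per_L"].unique())
    for kind in kinds:
        for band in bands:
            si0 = values_for(band, 0, kind)
            ctrl = {d: values_for(control_band, d, kind) for d in doses}
            for dose in doses:
                v = values_for(band, dose, kind)
                if v is None:
                    continue
                g_si = percent_gain(v, si0) if (si0 is not None and dose != 0) else np.full_like(times, np.nan)
                cb = ctrl.get(dose)
                g_wb = (
                    percent_gain(v, cb)
                    if (cb is not None and band != control_band)
                    else np.full_like(times, np.nan)
                )
                for i, t in enumerate(times):
                    rows.append(
                        {
                            "water_band": band,
                            "si_dose_mg_per_L": dose,
                            "response_kind": kind,
                            "time_h": t,
                            "gain_vs_si0_pct": g_si[i],
                            "gain_vs_control_band_pct": g_wb[i],
                        }
                    )
    return pd.DataFrame(rows)


def _holm(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Holm step-down rejections at family level alpha."""
    m = len(pvals)
    order = np.argsort(pvals)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def _anova_table(measurements: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """One-way ANOVA across Si doses, per water band x response kind x hour."""
    rows = []
    for (band, kind, t), chunk in measurements.groupby(["water_band", "response_kind", "time_h"], sort=True):
        groups = [g["value"].to_numpy() for _, g in chunk.groupby("si_dose_mg_per_L", sort=True)]
        try:
            f, p = anova_oneway(groups)
        except ValueError as exc:
            logger.warning("ANOVA skipped for %s/%s t=%s: %s", band, kind, t, exc)
            f, p = np.nan, np.nan
        rows.append(
            {"water_band": band, "response_kind": kind, "time_h": t, "F": f, "p": p}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if cfg.holm:
        sig = np.zeros(len(out), dtype=bool)
        for _, idx in out.groupby(["water_band", "response_kind"]).groups.items():
            pv = out.loc[idx, "p"].to_numpy()
            ok = ~np.isnan(pv)
            rej = np.zeros(len(pv), dtype=bool)
            if ok.any():
                rej[ok] = _holm(pv[ok], cfg.alpha)
            sig[np.asarray(idx)] = rej
        out["significant"] = sig
    else:
        out["significant"] = out["p"] < cfg.alpha
    return out


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Run every stage and write the report bundle under ``cfg.out_dir``.

    Writes ``measurements.csv`` (when simulated), ``climate.csv`` (idem),
    ``constants.csv``, ``exclusions.csv`` (cells that could not be fitted,
    with reasons), ``cumulative.csv``, ``percent_gain.csv``, ``anova.csv``
    and ``manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    climate_df = None
    if cfg.synthetic is not None:
        logger.info("simulating factorial experiment (seed=%s)", cfg.synthetic.seed)
        measurements = generate_experiment(cfg.synthetic)
        climate_df = generate_climate(cfg.synthetic).to_dataframe()
        write_measurements(measurements, out / "measurements.csv")
        climate_df.to_csv(out / "climate.csv", index=False)
        source = {"kind": "synthetic", "seed": cfg.synthetic.seed, "config_hash": cfg.synthetic.config_hash()}
    else:
        measurements = read_measurements(cfg.input_csv)
        source = {"kind": "csv", "path": str(cfg.input_csv)}

    try:  # fit every cell
        fits: FitTable = fit_all(measurements)
    except ValueError as exc:
        raise ValueError(f"fitting stage failed: {exc}") from exc
    for rec in fits.failures.itertuples(index=False):
        logger.warning(
            "cell excluded from constants table: %s/%s/%s -- %s",
            rec.water_band, rec.si_dose_mg_per_L, rec.response_kind, rec.reason,
        )

    try:
        cumulative = _cumulative_table(fits.constants, cfg)
    except ValueError as exc:
        raise ValueError(f"integration stage failed: {exc}") from exc
    try:
        gains = _gain_table(fits.constants, measurements, cfg)
    except ValueError as exc:
        raise ValueError(f"percent-gain stage failed: {exc}") from exc
    anova = _anova_table(measurements, cfg)

    float_fmt = "%.10g"
    fits.constants.to_csv(out / "constants.csv", index=False, float_format=float_fmt)
    fits.failures.to_csv(out / "exclusions.csv", index=False)
    cumulative.to_csv(out / "cumulative.csv", index=False, float_format=float_fmt)
    gains.to_csv(out / "percent_gain.csv", index=False, float_format=float_fmt)
    anova.to_csv(out / "anova.csv", index=False, float_format=float_fmt)

    import diurnalfit

    manifest = {
        "package": "diurnalfit",
        "version": diurnalfit.__version__,
        "source": source,
        "window": list(cfg.window),
        "step": cfg.step,
        "rule": cfg.rule,
        "alpha": cfg.alpha,
        "holm": cfg.holm,
        "gain_on": cfg.gain_on,
        "n_cells_fitted": int(len(fits.constants)),
        "n_cells_excluded": int(len(fits.failures)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return ReportBundle(
        measurements=measurements,
        constants=fits.constants,
        failures=fits.failures,
        cumulative=cumulative,
        gains=gains,
        anova=anova,
        manifest=manifest,
        climate=climate_df,
    )


def _configure_logging() -> None:
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
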