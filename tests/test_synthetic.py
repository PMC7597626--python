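"""Factorial experiment generator and diurnal microclimate."""

import math

import numpy as np
import pytest

from diurnalfit import (
    SI_DOSES,
    WATER_BANDS,
    DiurnalSeries,
    SyntheticConfig,
    TreatmentDesign,
    daily_total,
    evaluate_response,
    fit_linearized,
    generate_climate,
    generate_experiment,
    generate_gas_exchange,
    params_with_peak,
    peak_time,
    true_params_for,
    vpd_from,
)


# --------------------------------------------------------------------------
# microclimate
# --------------------------------------------------------------------------

def climate_at(profile, hour):
    idx = np.flatnonzero(np.isclose(profile.times, hour))
    assert idx.size == 1, f"hour {hour} not on climate grid"
    return int(idx[0])


def test_climate_reproduces_observed_anchors_exactly():
    c = generate_climate()
    assert c.rh[climate_at(c, 6.0)] == pytest.approx(88.0)
    assert c.rh[climate_at(c, 17.0)] == pytest.approx(36.0)
    assert c.ppfd[climate_at(c, 5.0)] == 0.0
    assert c.ppfd[climate_at(c, 19.0)] == 0.0


def test_climate_curve_shapes():
    c = generate_climate()
    assert np.all(c.ppfd >= 0)
    assert np.all((c.rh >= 0) & (c.rh <= 100))
    # humidity dries out through the afternoon, recovers after 15:00
    i6, i15, i17 = (climate_at(c, h) for h in (6.0, 15.0, 17.0))
    assert np.all(np.diff(c.rh[i6 : i15 + 1]) <= 0)
    assert np.all(np.diff(c.rh[i15 : i17 + 1]) >= 0)
    assert c.rh[i15] == c.rh.min()
    # PPFD plateau 11:00-15:00 at the daily maximum
    i11, i13 = climate_at(c, 11.0), climate_at(c, 13.0)
    assert c.ppfd[i11] == c.ppfd[i13] == c.ppfd.max()
    # evening warmer than dawn; temperature peak in early afternoon
    assert c.ta[climate_at(c, 19.0)] > c.ta[climate_at(c, 5.0)]
    t_peak = c.times[np.argmax(c.ta)]
    assert 13.0 <= t_peak <= 15.0
    # CO2 highest in early morning, dip around midday
    assert c.ca[0] == c.ca.max()
    assert 11.0 <= c.times[np.argmin(c.ca)] <= 15.0
    # VPD consistent with Ta and RH everywhere
    assert np.allclose(c.vpd, vpd_from(c.ta, c.rh))
    assert np.all(c.vpd >= 0)


def test_vpd_tetens_examples():
    assert vpd_from(31.0, 100.0) == 0.0
    es25 = 0.61078 * math.exp(17.27 * 25.0 / (25.0 + 237.3))
    assert vpd_from(25.0, 50.0) == pytest.approx(es25 / 2, rel=1e-12)
    # saturation pressure grows with temperature
    assert vpd_from(30.0, 50.0) > vpd_from(20.0, 50.0)
    with pytest.raises(ValueError, match="humidity"):
        vpd_from(25.0, 140.0)


# --------------------------------------------------------------------------
# treatment effects
# --------------------------------------------------------------------------

def test_control_cell_keeps_base_parameters(default_config):
    design = TreatmentDesign("100-95", 0)
    for kind in ("PN", "GS", "E"):
        assert true_params_for(design, default_config, kind) == default_config.base_params[kind]


def test_peak_time_is_invariant_across_treatments(default_config):
    peaks = {
        peak_time(true_params_for(TreatmentDesign(b, d), default_config, "PN"))
        for b in WATER_BANDS
        for d in SI_DOSES
    }
    assert peaks == {9.0}


def test_severe_stress_scales_daily_total_by_its_multiplier(default_config):
    """Amplitude-only treatment effects carry through the integral exactly."""
    control = true_params_for(TreatmentDesign("100-95", 0), default_config, "PN")
    severe = true_params_for(TreatmentDesign("35-30", 0), default_config, "PN")
    ratio = daily_total(severe, window=(7, 17)) / daily_total(control, window=(7, 17))
    assert ratio == pytest.approx(default_config.water_multipliers["35-30"], rel=1e-10)


def test_expected_values_preserve_treatment_ordering(default_config):
    """Control > mild > moderate > severe, and Si 300 > 500 > 100 > 0, at every hour."""
    times = np.array(TreatmentDesign("100-95", 0).sample_times)
    for kind in ("PN", "GS", "E"):
        by_band = [
            evaluate_response(true_params_for(TreatmentDesign(b, 0), default_config, kind), times)
            for b in WATER_BANDS
        ]
        for hi, lo in zip(by_band, by_band[1:]):
            assert np.all(hi > lo)
        by_dose = {
            d: evaluate_response(true_params_for(TreatmentDesign("55-50", d), default_config, kind), times)
            for d in SI_DOSES
        }
        assert np.all(by_dose[300] > by_dose[500])
        assert np.all(by_dose[500] > by_dose[100])
        assert np.all(by_dose[100] > by_dose[0])


def test_config_invariants_are_enforced():
    with pytest.raises(ValueError, match="control water band"):
        SyntheticConfig(water_multipliers={"100-95": 0.9, "80-75": 0.79, "55-50": 0.6, "35-30": 0.46})
    with pytest.raises(ValueError, match="strictly decrease"):
        SyntheticConfig(water_multipliers={"100-95": 1.0, "80-75": 0.6, "55-50": 0.79, "35-30": 0.46})
    with pytest.raises(ValueError, match="300 > 500 > 100"):
        SyntheticConfig(si_multipliers={0: 1.0, 100: 1.2, 300: 1.1, 500: 1.05})
    with pytest.raises(ValueError, match="noise_sigma_ln"):
        SyntheticConfig(noise_sigma_ln=-0.1)


def test_design_validation():
    with pytest.raises(ValueError, match="unknown water band"):
        TreatmentDesign("90-85", 0)
    with pytest.raises(ValueError, match="unknown Si dose"):
        TreatmentDesign("100-95", 200)
    with pytest.raises(ValueError, match="strictly increasing"):
        TreatmentDesign("100-95", 0, sample_times=(7.0, 7.0, 9.0))


# --------------------------------------------------------------------------
# gas-exchange tables
# --------------------------------------------------------------------------

def test_noise_free_measurements_lie_on_the_true_curve(noiseless_config):
    design = TreatmentDesign("80-75", 300)
    table = generate_gas_exchange(design, noiseless_config)
    for kind in ("PN", "GS", "E"):
        cell = table[table.response_kind == kind]
        truth = true_params_for(design, noiseless_config, kind)
        expected = evaluate_response(truth, cell.time_h.to_numpy())
        assert np.allclose(cell.value.to_numpy(), expected, rtol=1e-12)


def test_same_seed_reproduces_identical_tables(default_config):
    a = generate_experiment(default_config)
    b = generate_experiment(SyntheticConfig(seed=default_config.seed))
    assert a.equals(b)


def test_different_seeds_differ():
    a = generate_experiment(SyntheticConfig(seed=1))
    b = generate_experiment(SyntheticConfig(seed=2))
    assert not np.allclose(a.value.to_numpy(), b.value.to_numpy())


def test_experiment_table_covers_the_full_factorial(default_config):
    table = generate_experiment(default_config)
    assert len(table) == 4 * 4 * 5 * 6 * 3
    cells = table.groupby(["water_band", "si_dose_mg_per_L", "response_kind"]).size()
    assert len(cells) == 48 and set(cells) == {30}


def test_lognormal_noise_mean_matches_identity():
    """Mean of many noisy draws approaches value * exp(sigma^2 / 2)."""
    cfg = SyntheticConfig(seed=3, noise_sigma_ln=0.05)
    design = TreatmentDesign("100-95", 0, replicates=10_000)
    table = generate_gas_exchange(design, cfg)
    cell = table[(table.response_kind == "PN") & (table.time_h == 9.0)]
    truth = evaluate_response(true_params_for(design, cfg, "PN"), 9.0)
    expected_mean = truth * math.exp(cfg.noise_sigma_ln**2 / 2)
    assert cell.value.mean() == pytest.approx(expected_mean, rel=0.01)


def test_fit_round_trip_on_noisy_default_experiment(default_config):
    """sigma=0.05, 5 replicates: every fitted cell keeps r above 0.9."""
    from diurnalfit import fit_all

    fits = fit_all(generate_experiment(default_config))
    assert len(fits.constants) == 48
    assert fits.constants.r.min() > 0.9


def test_config_yaml_round_trip(tmp_path, default_config):
    p = tmp_path / "cfg.yaml"
    default_config.to_yaml(p)
    loaded = SyntheticConfig.from_yaml(p)
    assert loaded == default_config
    assert loaded.config_hash() == default_config.config_hash()


def test_params_with_peak_places_the_maximum():
    p = params_with_peak(-4.0, 36.0, 12.5)
    assert peak_time(p) == pytest.approx(9.0)
    assert evaluate_response(p, 9.0) == pytest.approx(12.5, rel=1e-12)
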