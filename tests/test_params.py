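"""Configuration loading, validation, and one-way sensitivity bounds."""

import dataclasses

import pytest
import yaml

from tdas_cea import params as P
from tdas_cea.params import (
    ALL_PARAM_NAMES,
    ConfigError,
    ParamSpec,
    load_params,
    owsa_bounds,
    validate,
    write_config,
)

# Independent enumeration of every published input row the model consumes.
EXPECTED_NAMES = {
    # diagnostic phase
    "p_test_positive", "p_true_positive", "p_false_positive",
    "p_delayed_tdas", "p_diagnosed_clin", "p_delayed_clin",
    # severity mixes at diagnosis
    "p_mild_tdas", "p_moderate_tdas", "p_severe_tdas",
    "p_mild_clin", "p_moderate_clin", "p_severe_clin",
    # annual severity transitions
    "tp_mild_to_moderate", "tp_mild_to_severe", "tp_moderate_to_mild",
    "tp_moderate_to_severe", "tp_severe_to_mild", "tp_severe_to_moderate",
    # mortality and utilities
    "rr_asd", "u_mild", "u_moderate", "u_severe",
    # direct medical
    "c_inpatient_mild", "c_inpatient_moderate", "c_inpatient_severe",
    "p_admission", "p_admitted_mild", "p_admitted_moderate", "p_admitted_severe",
    "c_outpatient_mild", "c_outpatient_moderate", "c_outpatient_severe",
    "c_instruments_mild", "c_instruments_moderate", "c_instruments_severe",
    "p_instruments_mild", "p_instruments_moderate", "p_instruments_severe",
    "c_activities_mild", "c_activities_moderate", "c_activities_severe",
    "p_activities_mild", "p_activities_moderate", "p_activities_severe",
    # direct non-medical
    "c_travel_outpatient", "c_food_outpatient", "c_accommodation_outpatient",
    "p_accommodation_outpatient",
    "n_outpatient_visits_mild", "n_outpatient_visits_moderate",
    "n_outpatient_visits_severe",
    "c_caregiver_outpatient",
    "c_travel_admission_patient", "c_food_admission_patient",
    "c_accommodation_admission_patient", "p_accommodation_admission",
    "c_travel_admission_caregiver", "c_food_admission_caregiver",
    "c_accommodation_admission_caregiver", "c_caregiver_admission",
    "n_admissions_per_year",
    # caregiver at home
    "c_hired_caregiver", "p_hired_caregiver", "c_lost_income",
    "p_quit_mild", "p_quit_moderate", "p_quit_severe",
    # diagnostic strategy costs
    "c_tdas_training", "c_tdas_instruments", "c_tdas_maintenance", "c_cloud",
    "c_labor_tdas", "c_labor_clin", "n_diagnoses_per_week",
    "n_amortization_diagnoses",
}


def test_every_input_row_maps_to_exactly_one_spec(params):
    assert set(ALL_PARAM_NAMES) == EXPECTED_NAMES
    assert len(ALL_PARAM_NAMES) == len(EXPECTED_NAMES) == 75
    assert set(params.specs) == EXPECTED_NAMES


@pytest.mark.parametrize(
    "name, mean, se, family",
    [
        ("p_test_positive", 0.8990, 0.0339, "beta"),
        ("p_true_positive", 0.8286, 0.0368, "beta"),
        ("rr_asd", 2.370, 0.0942, "lognormal"),
        ("tp_moderate_to_mild", 0.2643, 0.0226, "beta"),
        ("tp_mild_to_severe", 0.0, None, "fixed"),
        ("u_severe", 0.7930, 0.0177, "beta"),
        ("c_outpatient_moderate", 133.0, 7.0, "gamma"),
        ("c_activities_mild", 1314.0, 246.0, "gamma"),
        ("p_quit_severe", 0.2364, None, "fixed"),
        ("c_tdas_training", 151.0, None, "gamma"),
        ("n_diagnoses_per_week", 2.0, None, "fixed"),
    ],
)
def test_default_config_carries_published_values_verbatim(
    params, name, mean, se, family
):
    spec = params.specs[name]
    assert spec.mean == mean
    assert spec.se == se
    assert spec.family == family


def test_default_economic_settings(params):
    e = params.econ
    assert e.discount_rate == 0.03
    assert e.wtp_thb == 160_000.0
    assert e.exchange_rate == 34.995
    assert e.start_age == 3.52
    assert e.max_age == 100
    assert e.psa_iterations == 10_000
    assert e.wtp_usd == pytest.approx(4572.0817, abs=1e-3)


def test_wtp_override_selects_printed_value(params):
    e = dataclasses.replace(params.econ, wtp_usd_override=4577.0)
    assert e.wtp_usd == 4577.0


def test_scenario_mix_is_the_alternative_chart_review_mix(params):
    m = params.severity_mix("clin_scenario")
    assert (m.p_mild, m.p_moderate, m.p_severe) == (0.1139, 0.4557, 0.4304)


def test_missing_section_is_named(params):
    cfg = write_config(params)
    del cfg["utilities"]
    with pytest.raises(ConfigError, match="utilities"):
        load_params(cfg)


def test_missing_key_is_named(params):
    cfg = write_config(params)
    del cfg["diagnostic_phase"]["p_test_positive"]
    with pytest.raises(ConfigError, match="p_test_positive"):
        load_params(cfg)


def test_roundtrip_preserves_means_and_ses_exactly(params):
    again = load_params(write_config(params))
    for name in ALL_PARAM_NAMES:
        assert again.specs[name].mean == params.specs[name].mean
        assert again.specs[name].se == params.specs[name].se
        assert again.specs[name].family == params.specs[name].family


def test_yaml_roundtrip(tmp_path, params):
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(write_config(params)))
    again = load_params(path)
    assert again.specs == params.specs


def test_default_inputs_validate_clean(params):
    assert validate(params) == []


def test_validate_reports_bad_severity_mix(params):
    bad = params.with_means(
        {"p_mild_clin": 0.5, "p_moderate_clin": 0.5, "p_severe_clin": 0.5}
    )
    violations = validate(bad)
    assert any("sums to 1.5" in v for v in violations)


def test_validate_reports_out_of_range_life_table(params):
    lt = params.life_table.copy()
    lt.loc[40] = 1.2
    bad = dataclasses.replace(params, life_table=lt)
    violations = validate(bad)
    assert any("q(40)" in v for v in violations)


def test_validate_reports_excessive_transition_row(params):
    bad = params.with_means(
        {"tp_moderate_to_mild": 0.7, "tp_moderate_to_severe": 0.5}
    )
    assert any("moderate" in v for v in validate(bad))


# -- OWSA bounds ------------------------------------------------------------


@pytest.mark.parametrize(
    "spec, expected",
    [
        # reported SE: 95% CI mean +/- 1.96 se
        (ParamSpec("p_test_positive", 0.8990, 0.0339, "beta"), (0.832556, 0.965444)),
        # no SE: +/-20% of the mean
        (ParamSpec("c_tdas_training", 151.0, None, "gamma"), (120.8, 181.2)),
    ],
)
def test_owsa_bounds_examples(spec, expected):
    lo, hi = owsa_bounds(spec)
    assert lo == pytest.approx(expected[0], abs=1e-6)
    assert hi == pytest.approx(expected[1], abs=1e-6)


def test_owsa_bounds_clamped_to_unit_interval():
    lo, hi = owsa_bounds(ParamSpec("p_x", 0.9930, 0.02, "beta"))
    assert hi == 1.0
    assert lo == pytest.approx(0.9930 - 1.96 * 0.02)


def test_owsa_bounds_symmetric_before_clamping(params):
    for spec in params.specs.values():
        if spec.family == "fixed":
            continue
        lo, hi = owsa_bounds(spec)
        if lo > 0.0 and (not spec.unit_interval or hi < 1.0):  # unclamped
            assert lo + hi == pytest.approx(2.0 * spec.mean, rel=1e-12)


def test_owsa_bounds_rejects_fixed():
    with pytest.raises(ValueError, match="fixed"):
        owsa_bounds(ParamSpec("n_diagnoses_per_week", 2.0, None, "fixed"))
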