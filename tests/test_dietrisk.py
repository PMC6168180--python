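import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from snapsim.dietrisk import (
    MediatedEffectSpec,
    RiskModifierSet,
    junk_food_rr,
    load_mediated_spec,
    person_modifiers,
    rr_for_change,
)
from snapsim.policy import IntakeChangeSet


def test_rr_closed_form_at_reference_age():
    # RR 0.95 per 100 g/d, change +25.6 g/d: exp(ln 0.95 * 0.256)
    rr = rr_for_change(0.95, 100.0, 25.6, age=50, ref_age=50,
                       age_attenuation=0.15)
    assert rr == pytest.approx(np.exp(np.log(0.95) * 0.256))
    assert rr == pytest.approx(0.98696, abs=1e-5)


def test_rr_null_change_is_one():
    assert rr_for_change(0.8, 50.0, 0.0, age=70, age_attenuation=0.3) == 1.0


def test_attenuation_halving_gives_square_root():
    """If the log-RR halves by age 75, RR(75) = sqrt(RR(50)) for a unit change."""
    # attenuation 0.2/decade above ref 50: factor = 1 - 0.2*2.5 = 0.5 at 75
    rr50 = rr_for_change(0.9, 10.0, 10.0, age=50, ref_age=50, age_attenuation=0.2)
    rr75 = rr_for_change(0.9, 10.0, 10.0, age=75, ref_age=50, age_attenuation=0.2)
    assert rr75 == pytest.approx(np.sqrt(rr50))


def test_attenuation_floors_at_identity():
    rr = rr_for_change(0.9, 10.0, 10.0, age=200, ref_age=50, age_attenuation=0.5)
    assert rr == 1.0  # log-RR attenuated to zero, never crossing 1


def test_rr_rejects_nonpositive():
    with pytest.raises(ValueError):
        rr_for_change(0.0, 10.0, 1.0, age=50)


def test_age_monotonicity_of_log_rr():
    ages = np.linspace(35, 100, 40)
    rr = rr_for_change(0.9, 10.0, 5.0, age=ages, ref_age=50, age_attenuation=0.15)
    log_abs = np.abs(np.log(rr))
    assert (np.diff(log_abs) <= 1e-12).all()


def test_junk_composite_product_oracle():
    """Composite over two linked components equals the product of their RRs."""
    rr_table = pd.DataFrame([
        {"food": "a", "outcome": "chd", "rr_per_unit": 0.98, "unit_g_per_day": 1.0,
         "ref_age": 50, "age_attenuation": 0.0, "pathway": "direct"},
        {"food": "b", "outcome": "chd", "rr_per_unit": 1.01, "unit_g_per_day": 1.0,
         "ref_age": 50, "age_attenuation": 0.0, "pathway": "direct"},
    ])
    profile = pd.DataFrame([{"component": "a", "delta_per_gram": 1.0},
                            {"component": "b", "delta_per_gram": 1.0}])
    out = junk_food_rr(profile, np.array([1.0]), rr_table, np.array([50.0]))
    assert out["chd"][0] == pytest.approx(0.98 * 1.01)
    assert out["chd"][0] == pytest.approx(0.9898)
    # null change -> all component RRs 1 -> composite 1
    out0 = junk_food_rr(profile, np.array([0.0]), rr_table, np.array([50.0]))
    for o in out0.values():
        assert o[0] == 1.0


def test_junk_decrease_is_protective_for_chd(rr_table, junk_profile):
    """The default junk-food profile predicts CHD benefit when intake falls."""
    out = junk_food_rr(junk_profile, np.array([-11.5]), rr_table,
                       np.array([50.0]))
    assert out["chd"][0] < 1.0


def test_null_policy_gives_identity_modifiers(small_population, rr_table,
                                              mediated, junk_profile):
    cs = IntakeChangeSet({}, {"fruits": 81.3})
    mods = person_modifiers(small_population, cs, rr_table, mediated,
                            junk_profile)
    assert mods.is_identity()


def test_fv_only_change_leaves_diabetes_unchanged(small_population, rr_table,
                                                  mediated, junk_profile):
    """No F&V-diabetes etiologic effect: the diabetes RR stays exactly 1."""
    cs = IntakeChangeSet({"fruits": 0.234, "vegetables": 0.19},
                         {"fruits": 81.3, "vegetables": 134.8})
    mods = person_modifiers(small_population, cs, rr_table, mediated,
                            junk_profile)
    assert np.all(mods.rr_diabetes == 1.0)
    assert np.all(mods.delta_bmi == 0.0)
    assert np.all(mods.delta_sbp == 0.0)
    assert np.all(mods.rr_chd < 1.0)
    assert np.all(mods.rr_stroke < 1.0)


def test_log_additivity_of_combined_changes(small_population, rr_table,
                                            mediated, junk_profile):
    """Modifiers of a combined change equal the product of single-food RRs."""
    base = {"fruits": 81.3, "whole_grains": 13.9}
    cs_f = IntakeChangeSet({"fruits": 0.1}, base)
    cs_w = IntakeChangeSet({"whole_grains": 0.1}, base)
    cs_both = IntakeChangeSet({"fruits": 0.1, "whole_grains": 0.1}, base)
    args = (rr_table, mediated, junk_profile)
    m_f = person_modifiers(small_population, cs_f, *args)
    m_w = person_modifiers(small_population, cs_w, *args)
    m_b = person_modifiers(small_population, cs_both, *args)
    np.testing.assert_allclose(m_b.rr_chd, m_f.rr_chd * m_w.rr_chd, rtol=1e-12)
    np.testing.assert_allclose(m_b.rr_diabetes,
                               m_f.rr_diabetes * m_w.rr_diabetes, rtol=1e-12)


def test_ssb_bmi_stratum_slope(rr_table, mediated, junk_profile):
    """BMI shift = stratum slope x change in servings/day for an obese 50-y-old."""
    pop = pd.DataFrame({
        "age": [50.0], "sex": ["female"], "race_ethnicity": ["nh_black"],
        "sbp": [150.0], "bmi": [32.0], "diet_ssb": [414.0],
    })
    delta = -139.0
    cs = IntakeChangeSet({"ssb": delta / 414.0}, {"ssb": 414.0})
    mods = person_modifiers(pop, cs, rr_table, mediated, junk_profile)
    slope = 0.12  # ge50 / overweight_obese stratum (shipped table)
    assert mods.delta_bmi[0] == pytest.approx(slope * delta / 248.0)
    # mediated BMI factor applied on top of the direct BMI-independent terms
    assert mods.rr_diabetes[0] < 1.0


def test_unknown_stratum_errors(rr_table, junk_profile):
    med = load_mediated_spec()
    med.ssb_bmi_slopes = med.ssb_bmi_slopes.iloc[:1]  # drop strata
    pop = pd.DataFrame({
        "age": [70.0], "sex": ["male"], "race_ethnicity": ["other"],
        "sbp": [120.0], "bmi": [31.0], "diet_ssb": [100.0]})
    cs = IntakeChangeSet({"ssb": -0.3}, {"ssb": 100.0})
    with pytest.raises(KeyError):
        person_modifiers(pop, cs, rr_table, med, junk_profile)


def test_rr_clamped_for_extreme_deltas(rr_table, mediated, junk_profile):
    pop = pd.DataFrame({
        "age": [50.0], "sex": ["male"], "race_ethnicity": ["other"],
        "sbp": [120.0], "bmi": [22.0], "diet_processed_meat": [5000.0]})
    cs = IntakeChangeSet({"processed_meat": 1.0}, {"processed_meat": 5000.0})
    mods = person_modifiers(pop, cs, rr_table, mediated, junk_profile)
    # single-food factor capped at 2 per outcome; chd and diabetes both linked
    assert mods.rr_chd[0] <= 2.0 * (1 + 1e-12)
    assert mods.rr_diabetes[0] <= 2.0 * (1 + 1e-12)


@settings(max_examples=60, deadline=None)
@given(delta=st.floats(-50, 50), rr=st.floats(0.5, 1.9))
def test_rr_monotone_and_continuous_in_delta(delta, rr):
    v1 = rr_for_change(rr, 100.0, delta, age=55, ref_age=50, age_attenuation=0.1)
    v2 = rr_for_change(rr, 100.0, delta + 1.0, age=55, ref_age=50,
                       age_attenuation=0.1)
    if rr < 1:
        assert v2 <= v1 + 1e-12
    elif rr > 1:
        assert v2 >= v1 - 1e-12
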