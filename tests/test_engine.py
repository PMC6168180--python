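import numpy as np
import pandas as pd
import pytest

from snapsim.dietrisk import RiskModifierSet
from snapsim.engine import (
    EngineParams,
    HealthState,
    StateCosts,
    advance_cohort_markov,
    annual_cvd_risk,
    framingham_cvd_10y,
    simulate,
    ten_year_to_annual,
)


def test_ten_year_to_annual():
    assert ten_year_to_annual(0.0) == 0.0
    assert ten_year_to_annual(0.1) == pytest.approx(0.010481, abs=1e-6)
    assert ten_year_to_annual(0.5) == pytest.approx(0.066967, abs=1e-6)
    p = np.linspace(0, 0.9, 20)
    out = ten_year_to_annual(p)
    assert (np.diff(out) > 0).all() and (out <= p + 1e-15).all()
    with pytest.raises(ValueError):
        ten_year_to_annual(1.0)


def test_framingham_reference_profile():
    """Published general-CVD function: 61-y male, TC 180, HDL 47, SBP 124
    (untreated), smoker, non-diabetic. Frozen value computed from the
    published coefficients."""
    p10 = framingham_cvd_10y(61, True, 124, 180, 47, True, False)
    assert float(p10) == pytest.approx(0.23388, abs=1e-4)
    # female equation on the same profile
    p10f = framingham_cvd_10y(61, False, 124, 180, 47, True, False)
    assert float(p10f) == pytest.approx(0.10484, abs=1e-4)


def _person(**kw):
    base = dict(age=55.0, sex="male", sbp=130.0, total_chol=200.0, hdl=50.0,
                bmi=28.0, smoker=False, diabetic=False, weight=1.0)
    base.update(kw)
    return pd.DataFrame([base])


def test_annual_risk_monotone_in_risk_factors():
    params = EngineParams()
    r_low = annual_cvd_risk(_person(sbp=120.0), params)
    r_high = annual_cvd_risk(_person(sbp=160.0), params)
    assert r_high > r_low
    assert annual_cvd_risk(_person(smoker=True), params) > r_low
    assert annual_cvd_risk(_person(diabetic=True), params) > r_low
    assert annual_cvd_risk(_person(hdl=70.0), params) < annual_cvd_risk(
        _person(hdl=40.0), params)


def test_annual_risk_linear_in_modifier_and_calibration():
    params = EngineParams()
    base = annual_cvd_risk(_person(), params)
    assert annual_cvd_risk(_person(), params, rr_modifier=0.9) == pytest.approx(
        0.9 * base)
    params2 = EngineParams(calibration_multiplier=1.3)
    assert annual_cvd_risk(_person(), params2) == pytest.approx(1.3 * base)


def test_annual_risk_missing_factor_errors():
    df = _person().drop(columns=["hdl"])
    with pytest.raises(ValueError, match="hdl"):
        annual_cvd_risk(df, EngineParams())


def _cohort(n, **kw):
    person = dict(age=50.0, sex="male", sbp=130.0, total_chol=200.0, hdl=50.0,
                  bmi=28.0, smoker=False, diabetic=False, weight=1.0)
    person.update(kw)
    return pd.DataFrame([person] * n)


def test_zero_hazards_accrue_full_utility():
    params = EngineParams(constant_hazards={"p_noncvd_death": 0.0, "p_cvd": 0.0,
                                            "p_diabetes": 0.0},
                          utility_age_decrement=0.0,
                          diabetes_utility_multiplier=1.0)
    pop = _cohort(10)
    res = simulate(pop, RiskModifierSet.identity(10), [5], params, seed=1)
    t = res.tallies["5"]
    assert t.events_total == 0 and t.total_deaths == 0
    expected_qaly = 10 * sum(1 / 1.03 ** y for y in range(5))
    assert t.qalys == pytest.approx(expected_qaly)
    assert t.qalys_undiscounted == pytest.approx(50.0)
    assert t.person_years == pytest.approx(50.0)


def test_certain_fatal_mi():
    """Forced MI with case fatality 1 kills everyone in the first cycle."""
    params = EngineParams(
        constant_hazards={"p_noncvd_death": 0.0, "p_cvd": 1.0, "p_diabetes": 0.0},
        stroke_share=0.0, chd_split={"mi": 1.0, "angina": 0.0, "rca": 0.0},
        case_fatality={"mi": (1.0, 1.0), "stroke": (0.0, 0.0),
                       "angina": (0.0, 0.0), "rca": (0.0, 0.0)},
        max_event_prob=1.0)
    pop = _cohort(20)
    res = simulate(pop, RiskModifierSet.identity(20), [5], params, seed=1)
    t = res.tallies["5"]
    assert t.cvd_deaths == 20
    assert t.events_by_type["mi"] == 20
    assert t.events_total == 20
    assert t.person_years == pytest.approx(10.0)  # half-cycle in death year


def test_determinism_same_seed():
    pop = _cohort(500, age=60.0)
    params = EngineParams()
    mods = RiskModifierSet.identity(500)
    a = simulate(pop, mods, [5, 10], params, seed=9).tallies
    b = simulate(pop, mods, [5, 10], params, seed=9).tallies
    for h in a:
        assert a[h] == b[h]
    c = simulate(pop, mods, [5, 10], params, seed=10).tallies
    assert a["10"] != c["10"]


def test_invalid_horizon_and_empty_population():
    pop = _cohort(3)
    with pytest.raises(ValueError):
        simulate(pop, RiskModifierSet.identity(3), [7], EngineParams(), 1)
    with pytest.raises(ValueError):
        simulate(pop.iloc[:0], RiskModifierSet.identity(0), [5], EngineParams(), 1)


def test_discounted_qalys_below_person_years():
    pop = _cohort(200, age=45.0)
    res = simulate(pop, RiskModifierSet.identity(200), [20], EngineParams(), 4)
    t = res.tallies["20"]
    assert t.qalys < t.qalys_undiscounted <= t.person_years


def test_microsim_matches_markov_oracle():
    """Homogeneous constant-hazard cohort: microsimulation means match the
    closed-form Markov chain within 3 Monte-Carlo SEs at n = 50,000."""
    n = 50_000
    p_nc, p_cvd, cf, years = 0.01, 0.03, 0.3, 10
    u_well, u_chronic = 1.0, 0.8
    params = EngineParams(
        constant_hazards={"p_noncvd_death": p_nc, "p_cvd": p_cvd,
                          "p_diabetes": 0.0},
        case_fatality={t: (cf, cf) for t in ("mi", "stroke", "angina", "rca")},
        state_utility={int(s): (0.0 if s in (HealthState.DEAD_CVD,
                                             HealthState.DEAD_OTHER)
                                else u_well if s == HealthState.WELL
                                else u_chronic)
                       for s in HealthState},
        utility_age_decrement=0.0, diabetes_utility_multiplier=1.0,
        recurrent_multiplier=2.0)
    pop = _cohort(n, age=50.0)
    res = simulate(pop, RiskModifierSet.identity(n), [10], params, seed=123)
    t = res.tallies["10"]
    oracle = advance_cohort_markov(p_nc, p_cvd, cf, years, u_well, u_chronic,
                                   recurrent_multiplier=2.0, discount_rate=0.03)
    se_events = res.per_person["events"].std() / np.sqrt(n)
    se_qalys = res.per_person["qalys"].std() / np.sqrt(n)
    assert t.events_total / n == pytest.approx(oracle["events"],
                                               abs=3 * se_events)
    assert t.qalys / n == pytest.approx(oracle["qalys"], abs=3 * se_qalys)
    assert t.total_deaths / n == pytest.approx(oracle["deaths"], abs=0.01)


def test_common_random_numbers_couple_protective_modifier():
    """A protective CVD modifier averts a non-negative number of events at
    every horizon under common random numbers."""
    n = 5_000
    pop = _cohort(n, age=62.0, sbp=145.0)
    params = EngineParams()
    base = simulate(pop, RiskModifierSet.identity(n), [5, 10, 20], params, 77)
    mods = RiskModifierSet.identity(n)
    mods.rr_chd = np.full(n, 0.9)
    mods.rr_stroke = np.full(n, 0.9)
    scen = simulate(pop, mods, [5, 10, 20], params, 77)
    for h in ("5", "10", "20"):
        averted = base.tallies[h].events_total - scen.tallies[h].events_total
        assert averted >= 0
    assert base.tallies["20"].events_total > scen.tallies["20"].events_total


def test_stratified_output_sums_to_total(small_population):
    pop = small_population.copy()
    res = simulate(pop, RiskModifierSet.identity(len(pop)), [10],
                   EngineParams(), 5)
    strat = res.stratified(pop, "sex")
    assert strat["events_total"].sum() == pytest.approx(
        res.tallies["10"].events_total)
    assert strat["qalys"].sum() == pytest.approx(res.tallies["10"].qalys)


def test_scaled_tally():
    pop = _cohort(100, age=70.0)
    t = simulate(pop, RiskModifierSet.identity(100), [5],
                 EngineParams(), 2).tallies["5"]
    s = t.scaled(145.4)
    assert s.qalys == pytest.approx(t.qalys * 145.4)
    assert s.events_total == pytest.approx(t.events_total * 145.4)
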