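"""Annual-cycle individual state-transition model of CVD and type 2 diabetes.

Each simulated adult is followed in annual cycles until death or age 100.
Annual first/recurrent CVD risk is computed from the published sex-specific
Framingham general-CVD function (age, systolic blood pressure, total and HDL
cholesterol, smoking, diabetes), converted from 10-year to annual probability,
scaled by a calibration multiplier and by the scenario's per-person relative
risk modifiers. Competing risks are resolved by sequential conditional draws
within a cycle (non-CVD death, then a CVD event typed and possibly fatal, then
diabetes onset); acute events resolve to their chronic counterpart the next
cycle. QALYs and healthcare costs accrue annually with discounting.

Scenarios are compared with common random numbers: the uniform draws for each
person-year come from a stream keyed by (seed, year) only, so the base case
and every scenario see identical draws and incremental outcomes are free of
between-scenario Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd


class HealthState(IntEnum):
    WELL = 0
    ACUTE_MI = 1
    ACUTE_STROKE = 2
    POST_MI = 3
    POST_STROKE = 4
    ANGINA = 5
    RCA_SURVIVOR = 6
    DEAD_CVD = 7
    DEAD_OTHER = 8


CHRONIC_CVD_STATES = (HealthState.POST_MI, HealthState.POST_STROKE,
                      HealthState.ANGINA, HealthState.RCA_SURVIVOR)
DEAD_STATES = (HealthState.DEAD_CVD, HealthState.DEAD_OTHER)

EVENT_TYPES = ("mi", "stroke", "angina", "rca")

HORIZON_YEARS = {"5": 5, "10": 10, "20": 20}
VALID_HORIZONS = {5, 10, 20, "lifetime"}

# --- Framingham general-CVD 10-year risk (published sex-specific equations,
# untreated-SBP coefficients; the synthetic population carries no treatment
# flag). ---
_FRS = {
    "male": {"ln_age": 3.06117, "ln_tc": 1.12370, "ln_hdl": -0.93263,
             "ln_sbp": 1.93303, "smoker": 0.65451, "diabetic": 0.57367,
             "s0": 0.88936, "mean_lp": 23.9802},
    "female": {"ln_age": 2.32888, "ln_tc": 1.20904, "ln_hdl": -0.70833,
               "ln_sbp": 2.76157, "smoker": 0.52873, "diabetic": 0.69154,
               "s0": 0.95012, "mean_lp": 26.1931},
}


@dataclass
class StateCosts:
    """Direct healthcare costs (2017 USD): calibration inputs."""

    acute_event: dict[str, float] = field(default_factory=lambda: {
        "mi": 45_000.0, "stroke": 42_000.0, "angina": 15_000.0, "rca": 65_000.0})
    fatal_cvd_extra: float = 20_000.0
    chronic_annual: dict[int, float] = field(default_factory=lambda: {
        int(HealthState.POST_MI): 4_200.0, int(HealthState.POST_STROKE): 6_500.0,
        int(HealthState.ANGINA): 3_600.0, int(HealthState.RCA_SURVIVOR): 4_200.0})
    diabetes_annual: float = 3_000.0


@dataclass
class EngineParams:
    """Engine parameters. Defaults are calibration inputs (see docs/methods.md)."""

    calibration_multiplier: float = 1.0
    stroke_share: float = 0.35                      # share of first CVD events
    chd_split: dict[str, float] = field(default_factory=lambda: {
        "mi": 0.55, "angina": 0.35, "rca": 0.10})   # within CHD events
    # case fatality (under 65, 65 and over)
    case_fatality: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "mi": (0.25, 0.40), "stroke": (0.20, 0.35),
        "angina": (0.01, 0.02), "rca": (0.60, 0.70)})
    recurrent_multiplier: float = 2.0               # CVD hazard in chronic states
    # diabetes incidence: annual prob at age 50, BMI 27, with age/BMI gradients
    diabetes_base: float = 0.004
    diabetes_age_factor: float = 1.03
    diabetes_bmi_factor: float = 1.07
    diabetes_cap: float = 0.05
    # non-CVD mortality: q(age) = q35 * exp(b (age - 35)), capped
    noncvd_q35: dict[str, float] = field(default_factory=lambda: {
        "male": 0.0020, "female": 0.0013})
    noncvd_slope: float = 0.085
    noncvd_cap: float = 0.6
    # secular/age trends per simulated year
    sbp_drift: float = 0.35
    tc_drift: float = 0.40
    bmi_drift: float = 0.05
    # utilities (QALY weights), age-decremented multiplicatively
    state_utility: dict[int, float] = field(default_factory=lambda: {
        int(HealthState.WELL): 1.00, int(HealthState.ACUTE_MI): 0.80,
        int(HealthState.ACUTE_STROKE): 0.70, int(HealthState.POST_MI): 0.88,
        int(HealthState.POST_STROKE): 0.80, int(HealthState.ANGINA): 0.85,
        int(HealthState.RCA_SURVIVOR): 0.85,
        int(HealthState.DEAD_CVD): 0.0, int(HealthState.DEAD_OTHER): 0.0})
    utility_age_decrement: float = 0.0015           # per year above 35
    utility_floor: float = 0.40
    diabetes_utility_multiplier: float = 0.97
    discount_rate: float = 0.03
    max_age: float = 100.0
    max_event_prob: float = 0.95
    # degenerate/testing overrides: constant annual hazards replacing the
    # risk-score and incidence models (RR modifiers still apply)
    constant_hazards: dict[str, float] | None = None

    def validate(self) -> None:
        if abs(sum(self.chd_split.values()) - 1.0) > 1e-9:
            raise ValueError("chd_split proportions must sum to 1")
        for u in self.state_utility.values():
            if not (0.0 <= u <= 1.0):
                raise ValueError("utilities must lie in [0, 1]")
        for probs in list(self.case_fatality.values()):
            if any(not (0 <= p <= 1) for p in probs):
                raise ValueError("case fatality must lie in [0, 1]")

    def with_overrides(self, **kw) -> "EngineParams":
        return replace(self, **kw)


def ten_year_to_annual(p10):
    """Convert a 10-year event probability to an annual one (constant hazard)."""
    p10 = np.asarray(p10, dtype=float)
    if np.any(p10 >= 1.0) or np.any(p10 < 0.0):
        raise ValueError("p10 must lie in [0, 1)")
    return 1.0 - (1.0 - p10) ** 0.1


def framingham_cvd_10y(age, male, sbp, total_chol, hdl, smoker, diabetic):
    """Published Framingham general-CVD 10-year risk, vectorized."""
    age = np.asarray(age, dtype=float)
    male = np.asarray(male, dtype=bool)
    arrays = {"sbp": np.asarray(sbp, dtype=float),
              "total_chol": np.asarray(total_chol, dtype=float),
              "hdl": np.asarray(hdl, dtype=float)}
    for name, arr in arrays.items():
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"risk factor {name} missing or non-positive")
    smoker = np.asarray(smoker, dtype=float)
    diabetic = np.asarray(diabetic, dtype=float)
    out = np.empty(np.broadcast(age, male).shape, dtype=float)
    for sex, msk in (("male", male), ("female", ~male)):
        if not np.any(msk):
            continue
        c = _FRS[sex]
        lp = (c["ln_age"] * np.log(age) + c["ln_tc"] * np.log(arrays["total_chol"])
              + c["ln_hdl"] * np.log(arrays["hdl"])
              + c["ln_sbp"] * np.log(arrays["sbp"])
              + c["smoker"] * smoker + c["diabetic"] * diabetic)
        risk = 1.0 - c["s0"] ** np.exp(lp - c["mean_lp"])
        out[msk] = np.broadcast_to(risk, out.shape)[msk]
    return np.clip(out, 0.0, 0.999)


def annual_cvd_risk(population: pd.DataFrame, params: EngineParams,
                    rr_modifier=1.0) -> np.ndarray:
    """Annual CVD event probability per person: calibrated, modifier-scaled."""
    required = ("age", "sex", "sbp", "total_chol", "hdl", "smoker", "diabetic")
    missing = [c for c in required if c not in population]
    if missing:
        raise ValueError(f"population missing risk factors: {missing}")
    p10 = framingham_cvd_10y(
        population["age"].to_numpy(dtype=float),
        population["sex"].to_numpy() == "male",
        population["sbp"].to_numpy(dtype=float),
        population["total_chol"].to_numpy(dtype=float),
        population["hdl"].to_numpy(dtype=float),
        population["smoker"].to_numpy(dtype=float),
        population["diabetic"].to_numpy(dtype=float))
    p1 = ten_year_to_annual(p10) * params.calibration_multiplier * rr_modifier
    return np.clip(p1, 0.0, 1.0)


@dataclass
class TrajectoryTally:
    """Cumulative (weighted) outcomes of one simulated arm at one horizon."""

    n: int = 0
    years: int = 0
    events_total: float = 0.0
    events_by_type: dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in EVENT_TYPES})
    diabetes_cases: float = 0.0
    cvd_deaths: float = 0.0
    other_deaths: float = 0.0
    person_years: float = 0.0
    disc_person_years: float = 0.0
    qalys: float = 0.0            # discounted
    qalys_undiscounted: float = 0.0
    hc_cost: float = 0.0          # discounted

    @property
    def total_deaths(self) -> float:
        return self.cvd_deaths + self.other_deaths

    def scaled(self, factor: float) -> "TrajectoryTally":
        return TrajectoryTally(
            n=self.n, years=self.years,
            events_total=self.events_total * factor,
            events_by_type={k: v * factor for k, v in self.events_by_type.items()},
            diabetes_cases=self.diabetes_cases * factor,
            cvd_deaths=self.cvd_deaths * factor,
            other_deaths=self.other_deaths * factor,
            person_years=self.person_years * factor,
            disc_person_years=self.disc_person_years * factor,
            qalys=self.qalys * factor,
            qalys_undiscounted=self.qalys_undiscounted * factor,
            hc_cost=self.hc_cost * factor)


@dataclass
class SimulationResult:
    """Tallies per horizon plus per-person accumulators for stratified output."""

    tallies: dict[str, TrajectoryTally]
    per_person: dict[str, np.ndarray]
    horizon_years: dict[str, int]

    def stratified(self, population: pd.DataFrame, by: str) -> pd.DataFrame:
        codes, cats = pd.factorize(population[by])
        w = population["weight"].to_numpy(dtype=float)
        rows = []
        for i, cat in enumerate(cats):
            m = codes == i
            rows.append({
                by: cat,
                "events_total": float((w * self.per_person["events"])[m].sum()),
                "diabetes_cases": float((w * self.per_person["diabetes"])[m].sum()),
                "cvd_deaths": float((w * self.per_person["cvd_death"])[m].sum()),
                "qalys": float((w * self.per_person["qalys"])[m].sum()),
                "hc_cost": float((w * self.per_person["hc_cost"])[m].sum()),
            })
        return pd.DataFrame(rows)


def _noncvd_q(params: EngineParams, age: np.ndarray, male: np.ndarray) -> np.ndarray:
    q35 = np.where(male, params.noncvd_q35["male"], params.noncvd_q35["female"])
    return np.minimum(params.noncvd_cap, q35 * np.exp(params.noncvd_slope * (age - 35.0)))


def _utility(params: EngineParams, state: np.ndarray, age: np.ndarray,
             diabetic: np.ndarray) -> np.ndarray:
    lut = np.zeros(len(HealthState))
    for s, u in params.state_utility.items():
        lut[s] = u
    u = lut[state]
    agef = np.maximum(params.utility_floor,
                      1.0 - params.utility_age_decrement * np.maximum(age - 35.0, 0.0))
    u = u * agef
    return np.where(diabetic, u * params.diabetes_utility_multiplier, u)


def simulate(population: pd.DataFrame, modifiers, horizons, params: EngineParams,
             seed: int, costs: StateCosts | None = None) -> SimulationResult:
    """Run the annual-cycle microsimulation for one arm.

    ``modifiers`` is a :class:`snapsim.dietrisk.RiskModifierSet` (identity for
    the base case). ``horizons`` is an iterable drawn from {5, 10, 20,
    'lifetime'}. Draws are keyed by (seed, year) only, independent of the
    scenario, implementing common random numbers. Tallies are unweighted by
    national expansion; scale with :meth:`TrajectoryTally.scaled`.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    horizons = list(horizons)
    for h in horizons:
        if h not in VALID_HORIZONS:
            raise ValueError(f"invalid horizon {h!r}; use 5, 10, 20 or 'lifetime'")
    params.validate()
    if costs is None:
        costs = StateCosts()
    n = len(population)

    age = population["age"].to_numpy(dtype=float).copy()
    male = population["sex"].to_numpy() == "male"
    sbp = population["sbp"].to_numpy(dtype=float) + modifiers.delta_sbp
    tc = population["total_chol"].to_numpy(dtype=float).copy()
    hdl = population["hdl"].to_numpy(dtype=float)
    bmi = population["bmi"].to_numpy(dtype=float).copy()
    smoker = population["smoker"].to_numpy(dtype=bool)
    diabetic = population["diabetic"].to_numpy(dtype=bool).copy()
    weight = population["weight"].to_numpy(dtype=float)

    state = np.full(n, int(HealthState.WELL), dtype=np.int8)

    baseline_diabetic = diabetic.copy()

    max_years = int(np.ceil(params.max_age - age.min())) + 1
    year_horizons = sorted({h for h in horizons if h != "lifetime"})
    if year_horizons:
        max_explicit = max(year_horizons)
    else:
        max_explicit = 0
    total_years = max_years if "lifetime" in horizons else max_explicit

    # per-person accumulators
    acc = {k: np.zeros(n) for k in
           ("events", "diabetes", "cvd_death", "other_death", "person_years",
            "disc_person_years", "qalys", "qalys_undisc", "hc_cost")}
    events_by_type = {t: 0.0 for t in EVENT_TYPES}

    tallies: dict[str, TrajectoryTally] = {}

    def snapshot(label: str, years: int) -> None:
        tallies[label] = TrajectoryTally(
            n=n, years=years,
            events_total=float((weight * acc["events"]).sum()),
            events_by_type=dict(events_by_type),
            diabetes_cases=float((weight * acc["diabetes"]).sum()),
            cvd_deaths=float((weight * acc["cvd_death"]).sum()),
            other_deaths=float((weight * acc["other_death"]).sum()),
            person_years=float((weight * acc["person_years"]).sum()),
            disc_person_years=float((weight * acc["disc_person_years"]).sum()),
            qalys=float((weight * acc["qalys"]).sum()),
            qalys_undiscounted=float((weight * acc["qalys_undisc"]).sum()),
            hc_cost=float((weight * acc["hc_cost"]).sum()))

    chd_types = ("mi", "angina", "rca")
    chd_cum = np.cumsum([params.chd_split[t] for t in chd_types])

    for year in range(total_years):
        # acute states resolve to their chronic counterpart after one cycle
        state[state == HealthState.ACUTE_MI] = HealthState.POST_MI
        state[state == HealthState.ACUTE_STROKE] = HealthState.POST_STROKE

        alive = state < HealthState.DEAD_CVD
        active = alive & (age < params.max_age)
        if not active.any():
            # everyone dead or censored: snapshot remaining horizons below
            pass

        rng = np.random.default_rng([int(seed), year])
        U = rng.random((6, n))
        disc = 1.0 / (1.0 + params.discount_rate) ** year

        if params.constant_hazards is not None:
            ch = params.constant_hazards
            q_nc = np.full(n, ch.get("p_noncvd_death", 0.0))
            p_base = np.full(n, ch.get("p_cvd", 0.0))
            p_diab_base = np.full(n, ch.get("p_diabetes", 0.0))
        else:
            q_nc = _noncvd_q(params, age, male)
            p10 = framingham_cvd_10y(np.minimum(age, 95.0), male, sbp, tc, hdl,
                                     smoker, diabetic)
            p_base = ten_year_to_annual(p10) * params.calibration_multiplier
            p_diab_base = np.clip(
                params.diabetes_base
                * params.diabetes_age_factor ** (age - 50.0)
                * params.diabetes_bmi_factor ** (bmi - 27.0),
                0.0, params.diabetes_cap)

        chronic = np.isin(state, [int(s) for s in CHRONIC_CVD_STATES])
        p_base = np.where(chronic, p_base * params.recurrent_multiplier, p_base)
        p_chd = p_base * (1.0 - params.stroke_share) * modifiers.rr_chd
        p_str = p_base * params.stroke_share * modifiers.rr_stroke
        p_ev = np.minimum(p_chd + p_str, params.max_event_prob)

        die_other = active & (U[0] < q_nc)
        at_risk = active & ~die_other
        event = at_risk & (U[1] < p_ev)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_str = np.where(p_ev > 0, p_str / np.maximum(p_chd + p_str, 1e-300), 0.0)
        is_stroke = event & (U[2] < frac_str)
        is_chd = event & ~is_stroke
        type_idx = np.searchsorted(chd_cum, U[3])  # 0=mi, 1=angina, 2=rca

        etype = np.full(n, -1, dtype=np.int8)  # 0 mi, 1 stroke, 2 angina, 3 rca
        etype[is_stroke] = 1
        etype[is_chd & (type_idx == 0)] = 0
        etype[is_chd & (type_idx == 1)] = 2
        etype[is_chd & (type_idx == 2)] = 3

        old65 = age >= 65.0
        cf = np.zeros(n)
        for code, name in ((0, "mi"), (1, "stroke"), (2, "angina"), (3, "rca")):
            lo, hi = params.case_fatality[name]
            m = etype == code
            cf[m] = np.where(old65[m], hi, lo)
        fatal = event & (U[4] < cf)

        p_diab = np.clip(p_diab_base * modifiers.rr_diabetes, 0.0, 1.0)
        diab_onset = at_risk & ~event & ~diabetic & (U[5] < p_diab)

        # --- state transitions ---
        prev_state = state.copy()
        state[die_other] = HealthState.DEAD_OTHER
        state[fatal] = HealthState.DEAD_CVD
        nonfatal = event & ~fatal
        state[nonfatal & (etype == 0)] = HealthState.ACUTE_MI
        state[nonfatal & (etype == 1)] = HealthState.ACUTE_STROKE
        state[nonfatal & (etype == 2)] = HealthState.ANGINA
        state[nonfatal & (etype == 3)] = HealthState.RCA_SURVIVOR
        diabetic = diabetic | diab_onset

        # --- tallies ---
        acc["events"] += event
        for code, name in ((0, "mi"), (1, "stroke"), (2, "angina"), (3, "rca")):
            events_by_type[name] += float((weight * (event & (etype == code))).sum())
        acc["diabetes"] += diab_onset
        acc["cvd_death"] += fatal
        acc["other_death"] += die_other
        died = die_other | fatal
        py = np.where(active, np.where(died, 0.5, 1.0), 0.0)
        acc["person_years"] += py
        acc["disc_person_years"] += py * disc

        util = _utility(params, state, age, diabetic)
        util_prev = _utility(params, prev_state, age, diabetic)
        qaly = np.where(active, np.where(died, 0.5 * util_prev, util), 0.0)
        acc["qalys"] += qaly * disc
        acc["qalys_undisc"] += qaly

        cost = np.zeros(n)
        for code, name in ((0, "mi"), (1, "stroke"), (2, "angina"), (3, "rca")):
            cost += (event & (etype == code)) * costs.acute_event[name]
        cost += fatal * costs.fatal_cvd_extra
        chronic_cost = np.zeros(len(HealthState))
        for s, c in costs.chronic_annual.items():
            chronic_cost[s] = c
        cost += np.where(active & ~event & ~died, chronic_cost[state], 0.0)
        cost += np.where(active & diabetic & ~died, costs.diabetes_annual, 0.0)
        acc["hc_cost"] += cost * disc

        # --- ageing and risk-factor trends ---
        age = age + 1.0
        still = state < HealthState.DEAD_CVD
        sbp = np.where(still, sbp + params.sbp_drift, sbp)
        tc = np.where(still, tc + params.tc_drift, tc)
        bmi = np.where(still, bmi + params.bmi_drift, bmi)

        elapsed = year + 1
        if elapsed in year_horizons:
            snapshot(str(elapsed), elapsed)
        # conservation check: every person is in exactly one state
        assert len(state) == n

    if "lifetime" in horizons:
        snapshot("lifetime", total_years)
    # make sure all requested explicit horizons exist even if the loop ended early
    for h in year_horizons:
        if str(h) not in tallies:
            snapshot(str(h), h)

    per_person = {
        "events": acc["events"], "diabetes": acc["diabetes"],
        "cvd_death": acc["cvd_death"], "qalys": acc["qalys"],
        "hc_cost": acc["hc_cost"],
    }
    labels = {str(h): h for h in year_horizons}
    if "lifetime" in horizons:
        labels["lifetime"] = total_years
    return SimulationResult(tallies=tallies, per_person=per_person,
                            horizon_years=labels)


def advance_cohort_markov(p_noncvd: float, p_cvd: float, case_fatality: float,
                          years: int, utility_well: float, utility_chronic: float,
                          recurrent_multiplier: float, discount_rate: float
                          ) -> dict[str, float]:
    """Closed-form Markov expectations for a homogeneous constant-hazard cohort.

    Companion oracle for validating the microsimulation: states WELL, CHRONIC,
    DEAD with the engine's sequential-draw transition structure (non-CVD death
    first, then a CVD event fatal with probability ``case_fatality``; chronic
    persons face ``recurrent_multiplier`` times the event hazard). Returns
    expected events, deaths, and discounted QALYs per person. QALY accounting
    matches the engine: a full year at the end-of-year state, half a year at
    the pre-death state in the year of death, with the event year spent at the
    chronic utility (the engine's acute utilities are passed via
    ``utility_chronic`` if desired).
    """
    # state vector: [well, chronic, dead]
    v = np.array([1.0, 0.0, 0.0])
    events = 0.0
    qalys = 0.0
    deaths = 0.0
    for t in range(years):
        disc = 1.0 / (1.0 + discount_rate) ** t
        well, chronic, dead = v
        p_ev_w = min(p_cvd, 1.0)
        p_ev_c = min(p_cvd * recurrent_multiplier, 1.0)
        ev_w = well * (1 - p_noncvd) * p_ev_w
        ev_c = chronic * (1 - p_noncvd) * p_ev_c
        events += ev_w + ev_c
        die_nc = (well + chronic) * p_noncvd
        die_ev = (ev_w + ev_c) * case_fatality
        deaths += die_nc + die_ev
        new_chronic = chronic * (1 - p_noncvd) * (1 - p_ev_c * case_fatality) \
            + ev_w * (1 - case_fatality)
        new_well = well * (1 - p_noncvd) * (1 - p_ev_w)
        # survivors accrue a full year at their end-of-year state; the dying
        # accrue half a year at their pre-death state
        qalys += disc * (new_well * utility_well + new_chronic * utility_chronic)
        qalys += disc * 0.5 * (well * p_noncvd * utility_well
                               + chronic * p_noncvd * utility_chronic
                               + ev_w * case_fatality * utility_well
                               + ev_c * case_fatality * utility_chronic)
        v = np.array([new_well, new_chronic, dead + die_nc + die_ev])
    return {"events": events, "deaths": deaths, "qalys": qalys}
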