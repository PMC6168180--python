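"""Costing and cost-effectiveness: discounted cost accrual, net costs by
perspective, and ICERs.

Three perspectives are evaluated against the current-policy base case:

* ``societal`` — program administrative costs minus healthcare cost-savings;
  food subsidies/disincentives are an intra-societal transfer and excluded.
* ``govt_adults`` — adds net food subsidy costs for adult SNAP participants
  (age 35+).
* ``govt_all`` — adds net food subsidy costs for all SNAP participants;
  children and younger adults contribute subsidy costs only, never health
  benefits or healthcare savings.

All dollars are constant 2017 USD discounted at 3%/year. Healthcare state
costs, administrative schedules, and per-capita food spending are calibration
inputs; per-capita spending is back-solved so program costs land on the
published scale (5-year discounted fruit & vegetable subsidy for all
participants ~= $11.5B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from snapsim.engine import StateCosts, TrajectoryTally
from snapsim.population import ADULT_SHARE, SNAP_PARTICIPANTS_2017

PERSPECTIVES = ("societal", "govt_adults", "govt_all")

WTP_THRESHOLDS = (50_000.0, 150_000.0)

# Cumulative discounted administrative costs by scenario and horizon
# (startup + annual outreach/EBT processing/monitoring; near-flat schedule).
DEFAULT_ADMIN_SCHEDULE: dict[str, dict[str, float]] = {
    "fv_incentive": {"5": 125e6, "10": 144e6, "20": 167e6, "lifetime": 212e6},
    "fv_ssb_restrict": {"5": 149e6, "10": 185e6, "20": 230e6, "lifetime": 317e6},
    "snap_plus": {"5": 149e6, "10": 185e6, "20": 230e6, "lifetime": 316e6},
}

# SNAP-dollar spending, $/person-year, adult participants (calibration inputs).
DEFAULT_FOOD_SPEND: dict[str, float] = {
    "fruits": 91.1, "vegetables": 111.4, "nuts": 15.0, "whole_grains": 25.0,
    "fish": 90.0, "plant_oils": 60.0, "ssb": 260.0, "processed_meat": 150.0,
    "junk_food": 235.0,
}


@dataclass
class CostInputs:
    """Cost parameters (2017 USD)."""

    state_costs: StateCosts = field(default_factory=StateCosts)
    admin_schedule: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ADMIN_SCHEDULE.items()})
    per_capita_food_spend: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOOD_SPEND))
    nonadult_spend_ratio: float = 0.679
    participants_all: float = SNAP_PARTICIPANTS_2017
    adult_share: float = ADULT_SHARE
    discount_rate: float = 0.03

    @property
    def participants_adults(self) -> float:
        return self.participants_all * self.adult_share

    def validate(self) -> None:
        if not (0.0 <= self.discount_rate <= 0.1):
            raise ValueError("discount_rate must lie in [0, 0.1]")
        if any(v < 0 for v in self.per_capita_food_spend.values()):
            raise ValueError("food spending must be non-negative")


def discounted(amount: float, year_index: int, rate: float = 0.03) -> float:
    """Present value of ``amount`` accrued in year ``year_index`` (0-based)."""
    if year_index < 0:
        raise ValueError("year_index must be non-negative")
    return amount / (1.0 + rate) ** year_index


def discount_sum(years: int, rate: float = 0.03) -> float:
    """Sum of annual discount factors over ``years`` starting at year 0."""
    return float(sum(1.0 / (1.0 + rate) ** t for t in range(years)))


def food_program_cost(change_set, scenario, cost_inputs: CostInputs, scope: str,
                      horizon_years: int,
                      adult_disc_person_years: float | None = None) -> float:
    """Signed discounted food subsidy cost (negative = program revenue).

    Incentives cost ``incentive_rate`` per SNAP dollar spent on incentivized
    foods (spending scaled by the post-policy consumption change);
    disincentives return ``disincentive_rate`` per dollar spent on
    disincentivized foods; restricted foods yield no program savings. Adult
    spending accrues only over surviving (discounted) person-years when
    ``adult_disc_person_years`` (mean per baseline adult) is given; non-adult
    participants are a constant pool with full survival.
    """
    if scope not in ("adults_35plus", "all_participants"):
        raise ValueError(f"unknown scope {scope!r}")
    cost_inputs.validate()
    pct = change_set.pct_change
    spend = cost_inputs.per_capita_food_spend

    inc_rate, dis_rate = scenario.incentive_rate, scenario.disincentive_rate
    per_adult_year = 0.0
    for food in scenario.incentivized_foods:
        per_adult_year += inc_rate * spend[food] * (1.0 + pct.get(food, 0.0))
    for food in scenario.disincentivized_foods:
        per_adult_year -= dis_rate * spend[food] * (1.0 + pct.get(food, 0.0))
    # restricted foods: no subsidy paid, no program savings

    dsum = discount_sum(horizon_years, cost_inputs.discount_rate)
    if adult_disc_person_years is None:
        adult_disc_person_years = dsum
    total = per_adult_year * cost_inputs.participants_adults * adult_disc_person_years
    if scope == "all_participants":
        nonadults = cost_inputs.participants_all - cost_inputs.participants_adults
        total += (per_adult_year * cost_inputs.nonadult_spend_ratio
                  * nonadults * dsum)
    return total


def net_cost(perspective: str, admin: float, healthcare_savings: float,
             food_net_adults: float | None = None,
             food_net_all: float | None = None) -> float:
    """Net cost (intervention costs minus healthcare cost-savings) by perspective."""
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    base = admin - healthcare_savings
    if perspective == "societal":
        return base
    if perspective == "govt_adults":
        if food_net_adults is None:
            raise ValueError("govt_adults perspective requires food_net_adults")
        return base + food_net_adults
    if food_net_all is None:
        raise ValueError("govt_all perspective requires food_net_all")
    return base + food_net_all


COST_SAVING = "cost_saving"
DOMINATED = "dominated"


def icer(net_cost_value: float, delta_qaly: float):
    """ICER ($/QALY), or a flag when a ratio is not meaningful.

    Returns ``COST_SAVING`` when the intervention gains QALYs at negative net
    cost (dominant) and ``DOMINATED`` when it loses QALYs at positive net cost.
    """
    if delta_qaly == 0:
        raise ValueError("ICER undefined for zero QALY change")
    if delta_qaly > 0:
        return COST_SAVING if net_cost_value < 0 else net_cost_value / delta_qaly
    return DOMINATED if net_cost_value > 0 else net_cost_value / delta_qaly


def classify_icer(value) -> str:
    """Classification against $50,000 and $150,000/QALY willingness-to-pay."""
    if value == COST_SAVING:
        return "cost_saving"
    if value == DOMINATED:
        return "dominated"
    if value < WTP_THRESHOLDS[0]:
        return "very_cost_effective"
    if value < WTP_THRESHOLDS[1]:
        return "cost_effective"
    return "not_cost_effective"


@dataclass
class CEResult:
    """Incremental cost-effectiveness of one scenario at one horizon."""

    scenario: str
    horizon: str
    delta_qalys: float
    healthcare_savings: float
    admin_cost: float
    food_net_adults: float
    food_net_all: float
    net_cost: dict[str, float]
    icer: dict[str, object]
    classification: dict[str, str]
    events_averted: float = 0.0
    diabetes_averted: float = 0.0
    cvd_deaths_averted: float = 0.0

    def as_row(self) -> dict:
        row = {
            "scenario": self.scenario, "horizon": self.horizon,
            "cvd_events_averted": self.events_averted,
            "diabetes_cases_averted": self.diabetes_averted,
            "cvd_deaths_averted": self.cvd_deaths_averted,
            "qalys_gained": self.delta_qalys,
            "healthcare_savings_busd": round(self.healthcare_savings / 1e9, 2),
            "admin_cost_musd": round(self.admin_cost / 1e6, 1),
            "food_net_adults_busd": round(self.food_net_adults / 1e9, 2),
            "food_net_all_busd": round(self.food_net_all / 1e9, 2),
        }
        for p in PERSPECTIVES:
            v = self.icer[p]
            row[f"icer_{p}"] = v if isinstance(v, str) else round(v)
            row[f"class_{p}"] = self.classification[p]
        return row


def evaluate_cea(scenario, change_set, base_tally: TrajectoryTally,
                 scen_tally: TrajectoryTally, horizon_label: str,
                 horizon_years: int, expansion: float,
                 cost_inputs: CostInputs, admin_override: float | None = None
                 ) -> CEResult:
    """Assemble the incremental CEA for one scenario arm vs the base case.

    ``expansion`` scales per-simulated-person tallies to the national adult
    SNAP population. The scenario arm's discounted person-years drive adult
    subsidy accrual (survival-adjusted).
    """
    b, s = base_tally.scaled(expansion), scen_tally.scaled(expansion)
    dq = s.qalys - b.qalys
    savings = b.hc_cost - s.hc_cost
    if admin_override is not None:
        admin = admin_override
    else:
        admin = cost_inputs.admin_schedule[scenario.id][horizon_label]
    disc_py_mean = scen_tally.disc_person_years / scen_tally.n
    food_adults = food_program_cost(change_set, scenario, cost_inputs,
                                    "adults_35plus", horizon_years,
                                    adult_disc_person_years=disc_py_mean)
    food_all = food_program_cost(change_set, scenario, cost_inputs,
                                 "all_participants", horizon_years,
                                 adult_disc_person_years=disc_py_mean)
    nets = {
        "societal": net_cost("societal", admin, savings),
        "govt_adults": net_cost("govt_adults", admin, savings,
                                food_net_adults=food_adults),
        "govt_all": net_cost("govt_all", admin, savings, food_net_all=food_all),
    }
    icers = {p: (icer(nets[p], dq) if dq != 0 else float("nan"))
             for p in PERSPECTIVES}
    classes = {p: (classify_icer(icers[p]) if not (isinstance(icers[p], float)
                                                   and np.isnan(icers[p]))
                   else "undefined") for p in PERSPECTIVES}
    return CEResult(
        scenario=scenario.id, horizon=horizon_label, delta_qalys=dq,
        healthcare_savings=savings, admin_cost=admin,
        food_net_adults=food_adults, food_net_all=food_all,
        net_cost=nets, icer=icers, classification=classes,
        events_averted=b.events_total - s.events_total,
        diabetes_averted=b.diabetes_cases - s.diabetes_cases,
        cvd_deaths_averted=b.cvd_deaths - s.cvd_deaths)
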