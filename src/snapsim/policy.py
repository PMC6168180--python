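"""Policy-effect module: price instruments -> per-food overall intake changes.

Each scenario's price instruments (a 30% incentive, a 30% disincentive, or a
purchase restriction in SNAP) are converted into overall fractional intake
changes by composing four factors:

    delta% = price_response x snap_venue_share x snap_dollar_share x (1 - spend_shift)

i.e. the intake response to the price change, attenuated by the fraction of
the food acquired at SNAP-eligible venues, the fraction paid with SNAP
dollars, and the fraction of the response offset by shifting purchases to
non-SNAP dollars. A restriction removes all SNAP-dollar purchases
(price_response = -1) with a configurable substitution shift.

The shipped component table is calibrated so composite effects equal the
published overall effects (fruits +23.4%, vegetables +19.0%, SSB restriction
-33.2%, and the per-food changes of the combined incentive/disincentive
scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

FOOD_CATEGORIES = ["fruits", "vegetables", "nuts", "whole_grains", "fish",
                   "plant_oils", "ssb", "processed_meat", "junk_food"]

GRAMS_PER_OZ = 28.35
GRAMS_PER_CUP_EQUIVALENT = 100.0
GRAMS_PER_FL_OZ = 29.57


@dataclass(frozen=True)
class Scenario:
    """One SNAP policy scenario: which foods get which price instrument."""

    id: str
    incentive_rate: float = 0.30
    disincentive_rate: float = 0.30
    incentivized_foods: frozenset = frozenset()
    disincentivized_foods: frozenset = frozenset()
    restricted_foods: frozenset = frozenset()

    def __post_init__(self):
        sets = [self.incentivized_foods, self.disincentivized_foods,
                self.restricted_foods]
        all_foods = [f for s in sets for f in s]
        if len(all_foods) != len(set(all_foods)):
            raise ValueError("a food may appear in at most one instrument set")
        for r in (self.incentive_rate, self.disincentive_rate):
            if not (0 <= r < 1):
                raise ValueError("rates must lie in [0, 1)")

    @property
    def foods(self) -> frozenset:
        return (self.incentivized_foods | self.disincentivized_foods
                | self.restricted_foods)


def default_scenarios() -> dict[str, Scenario]:
    """The three modelled SNAP interventions."""
    fv = frozenset({"fruits", "vegetables"})
    healthy = fv | {"nuts", "whole_grains", "fish", "plant_oils"}
    unhealthy = frozenset({"ssb", "processed_meat", "junk_food"})
    return {
        "fv_incentive": Scenario("fv_incentive", incentivized_foods=fv),
        "fv_ssb_restrict": Scenario("fv_ssb_restrict", incentivized_foods=fv,
                                    restricted_foods=frozenset({"ssb"})),
        "snap_plus": Scenario("snap_plus", incentivized_foods=healthy,
                              disincentivized_foods=unhealthy),
    }


def load_effect_components(path=None) -> pd.DataFrame:
    """Load and validate the per-scenario, per-food effect-component table."""
    if path is None:
        path = resources.files("snapsim.data") / "effect_components.csv"
        with resources.as_file(path) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"scenario", "food", "instrument", "price_response",
                "snap_dollar_share", "snap_venue_share", "spend_shift"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"effect component table missing columns: {sorted(missing)}")
    for col in ("snap_dollar_share", "snap_venue_share", "spend_shift"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    bad = df[(df["instrument"] == "incentive") & (df["price_response"] < 0)]
    bad2 = df[(df["instrument"].isin(["disincentive", "restriction"]))
              & (df["price_response"] > 0)]
    if len(bad) or len(bad2):
        raise ValueError("price_response sign must match the instrument")
    return df


def overall_change_incentive(price_response: float, snap_dollar_share: float,
                             snap_venue_share: float, spend_shift: float) -> float:
    """Overall fractional intake change from a price incentive/disincentive."""
    for name, v in (("snap_dollar_share", snap_dollar_share),
                    ("snap_venue_share", snap_venue_share),
                    ("spend_shift", spend_shift)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return price_response * snap_venue_share * snap_dollar_share * (1 - spend_shift)


def overall_change_restriction(snap_retail_share: float, shift: float) -> float:
    """Overall fractional intake change when a food is removed from SNAP eligibility.

    ``snap_retail_share`` is the fraction of overall intake purchased at retail
    with SNAP dollars; ``shift`` is the fraction of those purchases consumers
    move to non-SNAP dollars instead of forgoing.
    """
    if not (0 <= snap_retail_share <= 1) or not (0 <= shift <= 1):
        raise ValueError("snap_retail_share and shift must lie in [0, 1]")
    return -snap_retail_share * (1 - shift)


def _row_change(row: pd.Series) -> float:
    if row["instrument"] == "restriction":
        share = abs(row["price_response"]) * row["snap_dollar_share"] \
            * row["snap_venue_share"]
        return overall_change_restriction(share, row["spend_shift"])
    return overall_change_incentive(row["price_response"], row["snap_dollar_share"],
                                    row["snap_venue_share"], row["spend_shift"])


def scenario_changes(scenario: Scenario, components: pd.DataFrame) -> dict[str, float]:
    """Per-food overall fractional intake change for a scenario."""
    rows = components[components["scenario"] == scenario.id]
    changes: dict[str, float] = {}
    for food in sorted(scenario.foods):
        sub = rows[rows["food"] == food]
        if len(sub) == 0:
            raise ValueError(f"no effect components for food {food!r} in "
                             f"scenario {scenario.id!r}")
        pct = _row_change(sub.iloc[0])
        if food in scenario.disincentivized_foods | scenario.restricted_foods:
            if pct > 0:
                raise ValueError(f"disincentivized/restricted food {food!r} has "
                                 "a positive change")
        changes[food] = pct
    return changes


@dataclass
class IntakeChangeSet:
    """Per-food overall fractional changes and the implied absolute changes."""

    pct_change: dict[str, float]
    baseline: dict[str, float]
    abs_change: dict[str, float] = field(init=False)

    def __post_init__(self):
        self.abs_change = {f: self.pct_change.get(f, 0.0) * self.baseline[f]
                           for f in self.baseline}


def apply_scenario(diet: pd.DataFrame | dict[str, float], scenario: Scenario,
                   components: pd.DataFrame
                   ) -> tuple[IntakeChangeSet, pd.DataFrame | dict[str, float]]:
    """Shift a baseline diet by a scenario's overall per-food changes.

    ``diet`` is either a mapping food -> mean g/day, or a population DataFrame
    with ``diet_<food>`` columns; the same fractional change applies uniformly
    to every person (the policy response is modelled as an average), with no
    lag from intervention onset. Returns the change set (evaluated at the
    mean baseline) and the shifted diet.
    """
    pct = scenario_changes(scenario, components)
    if isinstance(diet, pd.DataFrame):
        baseline = {f: float(diet[f"diet_{f}"].mean()) for f in FOOD_CATEGORIES
                    if f"diet_{f}" in diet}
        shifted = diet.copy()
        for food, p in pct.items():
            shifted[f"diet_{food}"] = np.maximum(diet[f"diet_{food}"] * (1 + p), 0.0)
        return IntakeChangeSet(pct, baseline), shifted
    baseline = dict(diet)
    shifted_map = {f: max(v * (1 + pct.get(f, 0.0)), 0.0) for f, v in baseline.items()}
    return IntakeChangeSet(pct, baseline), shifted_map


# 2015 Dietary Guidelines recommendations used for context (2,000 kcal/d diet).
DGA_RECOMMENDATIONS = {
    "fruits": ("cup", 2.0, "day"),
    "vegetables": ("cup", 2.5, "day"),
    "nuts": ("oz", 5.0, "week"),
    "whole_grains": ("oz", 3.0, "day"),
    "fish": ("oz", 8.0, "week"),
}


def dga_fraction(change_g_per_day: float, amount: float, unit: str,
                 period: str = "day") -> float:
    """Express a g/day intake change as a fraction of a dietary recommendation."""
    if amount <= 0:
        raise ValueError("recommendation amount must be positive")
    if unit == "oz":
        grams = amount * GRAMS_PER_OZ
    elif unit == "cup":
        grams = amount * GRAMS_PER_CUP_EQUIVALENT
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if period == "week":
        grams /= 7.0
    elif period != "day":
        raise ValueError(f"unknown period {period!r}")
    return change_g_per_day / grams
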