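"""Diet-disease module: intake changes -> relative-risk multipliers and
risk-factor shifts.

Comparative risk assessment conventions: each food x outcome association is a
log-linear dose-response (relative risk per standard unit of daily intake)
whose log-RR attenuates linearly with age above a reference age. Junk food has
no single etiologic effect; its impact is the composite of nine joint
associations with other dietary components (some harmful, some beneficial).
SSBs act both directly (BMI-independent RRs) and through a BMI-mediated
pathway (kg/m^2 per serving/day, stratified by age and adiposity); dietary
sodium acts on systolic blood pressure (mmHg per g/day, stratified by age,
race, and hypertension status).

All default parameter files shipped under ``snapsim/data`` are calibration
inputs drawn from the comparative-risk-assessment literature; they are
validated on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

OUTCOMES = ("chd", "stroke", "diabetes")

SSB_SERVING_G = 248.0  # one 8-oz serving

# RR per kg/m^2 of BMI, applied to the BMI shift induced by SSB changes.
DEFAULT_BMI_OUTCOME_RR = {"chd": 1.06, "stroke": 1.04, "diabetes": 1.23}

# Per-food, per-outcome clamp on the RR induced by a single simulated change;
# guards against extreme synthetic intake deltas.
DEFAULT_RR_CLAMP = (0.5, 2.0)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("snapsim.data") / name) as p:
        return pd.read_csv(p)


def load_rr_table(path=None) -> pd.DataFrame:
    df = _read_packaged("rr_table.csv") if path is None else pd.read_csv(path)
    required = {"food", "outcome", "rr_per_unit", "unit_g_per_day", "ref_age",
                "age_attenuation", "pathway"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rr table missing columns: {sorted(missing)}")
    if (df["rr_per_unit"] <= 0).any():
        raise ValueError("rr_per_unit must be positive")
    if (df["unit_g_per_day"] <= 0).any():
        raise ValueError("unit_g_per_day must be positive")
    if (~df["outcome"].isin(OUTCOMES)).any():
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    if (df["age_attenuation"] < 0).any():
        raise ValueError("age_attenuation must be non-negative")
    return df


def load_junk_food_profile(path=None) -> pd.DataFrame:
    df = (_read_packaged("junk_food_profile.csv") if path is None
          else pd.read_csv(path))
    if not {"component", "delta_per_gram"} <= set(df.columns):
        raise ValueError("junk food profile needs component, delta_per_gram")
    return df


@dataclass
class MediatedEffectSpec:
    """Mediated pathways: SSB -> BMI and sodium -> SBP, with strata tables."""

    ssb_bmi_slopes: pd.DataFrame
    sodium_sbp_slopes: pd.DataFrame
    bmi_outcome_rr: dict[str, float]
    ssb_serving_g: float = SSB_SERVING_G

    def validate(self) -> None:
        need = {("lt50", "normal"), ("lt50", "overweight_obese"),
                ("ge50", "normal"), ("ge50", "overweight_obese")}
        have = set(zip(self.ssb_bmi_slopes["age_band"],
                       self.ssb_bmi_slopes["adiposity"]))
        if not need <= have:
            raise ValueError("ssb_bmi_slopes strata do not cover the population")
        need_na = {"35-49", "50-64", "65plus"}
        if not need_na <= set(self.sodium_sbp_slopes["age_band"]):
            raise ValueError("sodium_sbp_slopes age strata incomplete")
        for df, col in ((self.ssb_bmi_slopes, "slope_kg_m2_per_serving"),
                        (self.sodium_sbp_slopes, "slope_mmhg_per_g")):
            if not np.isfinite(df[col]).all():
                raise ValueError("mediated-effect slopes must be finite")


def load_mediated_spec(ssb_path=None, sodium_path=None,
                       bmi_outcome_rr: dict[str, float] | None = None
                       ) -> MediatedEffectSpec:
    spec = MediatedEffectSpec(
        ssb_bmi_slopes=(_read_packaged("ssb_bmi_slopes.csv") if ssb_path is None
                        else pd.read_csv(ssb_path)),
        sodium_sbp_slopes=(_read_packaged("sodium_sbp_slopes.csv")
                           if sodium_path is None else pd.read_csv(sodium_path)),
        bmi_outcome_rr=dict(bmi_outcome_rr or DEFAULT_BMI_OUTCOME_RR),
    )
    spec.validate()
    return spec


def rr_for_change(rr_per_unit: float, unit_g_per_day: float, delta,
                  age, ref_age: float = 50.0,
                  age_attenuation: float = 0.0):
    """Relative-risk multiplier for an intake change of ``delta`` g/day.

    RR = exp( ln(rr_at_age) * delta / unit ), with the log-RR attenuated
    linearly per decade of age above ``ref_age`` (floored at zero so the RR
    never crosses 1). Vectorized over ``delta`` and ``age``.
    """
    if rr_per_unit <= 0:
        raise ValueError("rr_per_unit must be positive")
    delta = np.asarray(delta, dtype=float)
    age = np.asarray(age, dtype=float)
    atten = np.maximum(0.0, 1.0 - age_attenuation
                       * np.maximum(0.0, age - ref_age) / 10.0)
    log_rr_age = np.log(rr_per_unit) * atten
    return np.exp(log_rr_age * delta / unit_g_per_day)


def _direct_entries(rr_table: pd.DataFrame, food: str, outcome: str) -> pd.DataFrame:
    return rr_table[(rr_table["food"] == food) & (rr_table["outcome"] == outcome)
                    & (rr_table["pathway"] == "direct")]


def junk_food_rr(profile: pd.DataFrame, delta_junk, rr_table: pd.DataFrame,
                 age) -> dict[str, np.ndarray]:
    """Composite per-outcome RR for a junk-food intake change.

    The change in junk food induces joint changes in the profiled dietary
    components; the composite RR is the product of the component RRs (only
    dietary components with direct RR entries contribute; sodium acts on SBP
    and is handled by :func:`person_modifiers`).
    """
    delta_junk = np.asarray(delta_junk, dtype=float)
    age = np.asarray(age, dtype=float)
    out = {o: np.ones(np.broadcast(delta_junk, age).shape) for o in OUTCOMES}
    for _, row in profile.iterrows():
        comp = row["component"]
        if comp == "sodium":
            continue
        comp_delta = row["delta_per_gram"] * delta_junk
        for outcome in OUTCOMES:
            entries = _direct_entries(rr_table, comp, outcome)
            if len(entries) == 0:
                continue
            e = entries.iloc[0]
            out[outcome] = out[outcome] * rr_for_change(
                e["rr_per_unit"], e["unit_g_per_day"], comp_delta, age,
                e["ref_age"], e["age_attenuation"])
    return out


@dataclass
class RiskModifierSet:
    """Per-person multiplicative RRs and additive risk-factor shifts."""

    rr_chd: np.ndarray
    rr_stroke: np.ndarray
    rr_diabetes: np.ndarray
    delta_bmi: np.ndarray
    delta_sbp: np.ndarray

    @classmethod
    def identity(cls, n: int) -> "RiskModifierSet":
        one = np.ones(n)
        zero = np.zeros(n)
        return cls(one.copy(), one.copy(), one.copy(), zero.copy(), zero.copy())

    def is_identity(self) -> bool:
        return (np.all(self.rr_chd == 1) and np.all(self.rr_stroke == 1)
                and np.all(self.rr_diabetes == 1) and np.all(self.delta_bmi == 0)
                and np.all(self.delta_sbp == 0))


def _ssb_bmi_slope_lookup(mediated: MediatedEffectSpec, age: np.ndarray,
                          bmi: np.ndarray) -> np.ndarray:
    tbl = {(r["age_band"], r["adiposity"]): r["slope_kg_m2_per_serving"]
           for _, r in mediated.ssb_bmi_slopes.iterrows()}
    band = np.where(age < 50, "lt50", "ge50")
    adip = np.where(bmi < 25, "normal", "overweight_obese")
    out = np.empty(len(age))
    for b in ("lt50", "ge50"):
        for a in ("normal", "overweight_obese"):
            m = (band == b) & (adip == a)
            if m.any():
                if (b, a) not in tbl:
                    raise KeyError(f"unknown SSB-BMI stratum {(b, a)}")
                out[m] = tbl[(b, a)]
    return out


def _sodium_sbp_slope_lookup(mediated: MediatedEffectSpec, age: np.ndarray,
                             race: np.ndarray, sbp: np.ndarray) -> np.ndarray:
    tbl = {(r["age_band"], r["race"], r["hypertensive"]): r["slope_mmhg_per_g"]
           for _, r in mediated.sodium_sbp_slopes.iterrows()}
    band = np.select([age < 50, age < 65], ["35-49", "50-64"], "65plus")
    rc = np.where(race == "nh_black", "nh_black", "other")
    htn = np.where(sbp >= 140, "yes", "no")
    out = np.empty(len(age))
    for b in ("35-49", "50-64", "65plus"):
        for r_ in ("nh_black", "other"):
            for h in ("yes", "no"):
                m = (band == b) & (rc == r_) & (htn == h)
                if m.any():
                    if (b, r_, h) not in tbl:
                        raise KeyError(f"unknown sodium-SBP stratum {(b, r_, h)}")
                    out[m] = tbl[(b, r_, h)]
    return out


def person_modifiers(population: pd.DataFrame, changes, rr_table: pd.DataFrame,
                     mediated: MediatedEffectSpec,
                     junk_profile: pd.DataFrame | None = None,
                     rr_clamp: tuple[float, float] = DEFAULT_RR_CLAMP
                     ) -> RiskModifierSet:
    """Per-person outcome RRs and risk-factor shifts for a set of diet changes.

    ``changes`` is an :class:`snapsim.policy.IntakeChangeSet`; its fractional
    changes are applied to each person's own baseline intakes, so absolute
    deltas (and hence RRs) vary across persons. Direct food RRs, the junk-food
    composite, and the BMI-mediated SSB pathway each contribute multiplicative
    factors (clamped per food x outcome); SSB->BMI and junk-sodium->SBP shifts
    are returned for the engine's risk factors.
    """
    n = len(population)
    age = population["age"].to_numpy(dtype=float)
    mods = RiskModifierSet.identity(n)
    pct = changes.pct_change
    if not pct:
        return mods
    lo, hi = rr_clamp

    log_rr = {o: np.zeros(n) for o in OUTCOMES}
    for food, p in pct.items():
        if p == 0.0:
            continue
        delta = p * population[f"diet_{food}"].to_numpy(dtype=float)
        if food == "junk_food":
            if junk_profile is None:
                raise ValueError("junk_food change requires a junk-food profile")
            comp = junk_food_rr(junk_profile, delta, rr_table, age)
            for o in OUTCOMES:
                log_rr[o] += np.log(np.clip(comp[o], lo, hi))
            # sodium pathway: junk-induced sodium change shifts SBP
            sod = junk_profile.loc[junk_profile["component"] == "sodium",
                                   "delta_per_gram"]
            if len(sod):
                d_sodium = float(sod.iloc[0]) * delta
                slope = _sodium_sbp_slope_lookup(
                    mediated, age, population["race_ethnicity"].to_numpy(),
                    population["sbp"].to_numpy(dtype=float))
                mods.delta_sbp = mods.delta_sbp + slope * d_sodium
            continue
        for outcome in OUTCOMES:
            entries = _direct_entries(rr_table, food, outcome)
            if len(entries) == 0:
                continue
            e = entries.iloc[0]
            rr = rr_for_change(e["rr_per_unit"], e["unit_g_per_day"], delta, age,
                               e["ref_age"], e["age_attenuation"])
            log_rr[outcome] += np.log(np.clip(rr, lo, hi))
        if food == "ssb":
            # BMI-mediated pathway, additional to (disjoint from) the direct
            # BMI-independent SSB terms above.
            slope = _ssb_bmi_slope_lookup(mediated, age,
                                          population["bmi"].to_numpy(dtype=float))
            d_bmi = slope * delta / mediated.ssb_serving_g
            mods.delta_bmi = mods.delta_bmi + d_bmi
            for outcome in OUTCOMES:
                rr = mediated.bmi_outcome_rr[outcome] ** d_bmi
                log_rr[outcome] += np.log(np.clip(rr, lo, hi))

    mods.rr_chd = np.exp(log_rr["chd"])
    mods.rr_stroke = np.exp(log_rr["stroke"])
    mods.rr_diabetes = np.exp(log_rr["diabetes"])
    return mods
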