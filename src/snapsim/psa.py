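"""Probabilistic sensitivity analysis.

Joint Monte-Carlo propagation of parameter uncertainty through the whole
pipeline: each iteration draws one coherent override set (policy effect sizes,
diet-disease relative risks, baseline CVD risk calibration, administrative and
healthcare and food unit costs, utility weights), re-runs the base case and
every scenario on a fixed reduced population with common random numbers, and
records incremental QALYs and net costs per perspective. Summaries report
medians, 2.5th/97.5th percentiles (linear interpolation between order
statistics), the fraction of iterations that are cost-saving, and fractions
below the willingness-to-pay thresholds.

Distribution families follow standard CEA practice: lognormal for relative
risks, truncated normal for effect sizes, gamma for costs, and bounded
multipliers for utility decrements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from snapsim import cea as cea_mod
from snapsim.cea import PERSPECTIVES, CostInputs, evaluate_cea
from snapsim.dietrisk import person_modifiers, RiskModifierSet
from snapsim.engine import EngineParams, StateCosts, simulate
from snapsim.policy import IntakeChangeSet, scenario_changes


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain input: a named parameter path and its distribution."""

    path: str
    family: str  # normal | lognormal | gamma | beta | uniform
    params: tuple
    bounds: tuple[float, float] = (-np.inf, np.inf)

    def draw(self, rng: np.random.Generator, max_retries: int = 1000) -> float:
        for _ in range(max_retries):
            if self.family == "normal":
                mu, sd = self.params
                x = mu if sd == 0 else rng.normal(mu, sd)
            elif self.family == "lognormal":
                median, sigma = self.params
                x = median if sigma == 0 else median * np.exp(rng.normal(0.0, sigma))
            elif self.family == "gamma":
                mean, cv = self.params
                if cv == 0:
                    x = mean
                else:
                    shape = 1.0 / cv ** 2
                    x = rng.gamma(shape, mean / shape)
            elif self.family == "beta":
                a, b = self.params
                x = rng.beta(a, b)
            elif self.family == "uniform":
                lo, hi = self.params
                x = rng.uniform(lo, hi)
            else:
                raise ValueError(f"unknown family {self.family!r}")
            if self.bounds[0] <= x <= self.bounds[1]:
                return float(x)
        raise RuntimeError(f"could not draw {self.path} within bounds "
                           f"{self.bounds} after {max_retries} tries")


def default_registry() -> list[ParameterDistribution]:
    """Default uncertainty distributions, centered on the point estimates."""
    return [
        ParameterDistribution("policy.effect_multiplier", "normal", (1.0, 0.10),
                              (0.3, 1.7)),
        ParameterDistribution("dietrisk.log_rr_multiplier", "normal", (1.0, 0.15),
                              (0.3, 1.7)),
        ParameterDistribution("engine.calibration_multiplier", "lognormal",
                              (1.0, 0.10), (0.3, 3.0)),
        ParameterDistribution("costs.admin_multiplier", "gamma", (1.0, 0.20),
                              (0.0, np.inf)),
        ParameterDistribution("costs.healthcare_multiplier", "gamma", (1.0, 0.20),
                              (0.0, np.inf)),
        ParameterDistribution("costs.food_spend_multiplier", "gamma", (1.0, 0.10),
                              (0.0, np.inf)),
        ParameterDistribution("engine.disutility_multiplier", "gamma", (1.0, 0.20),
                              (0.0, 3.0)),
    ]


def draw_parameter_set(registry: list[ParameterDistribution],
                       rng: np.random.Generator) -> dict[str, float]:
    """One coherent override set; draws are independent across parameters."""
    return {dist.path: dist.draw(rng) for dist in registry}


def _scaled_state_costs(costs: StateCosts, m: float) -> StateCosts:
    return StateCosts(
        acute_event={k: v * m for k, v in costs.acute_event.items()},
        fatal_cvd_extra=costs.fatal_cvd_extra * m,
        chronic_annual={k: v * m for k, v in costs.chronic_annual.items()},
        diabetes_annual=costs.diabetes_annual * m)


def _perturbed_utilities(params: EngineParams, m: float) -> dict[int, float]:
    out = {}
    for s, u in params.state_utility.items():
        if u == 0.0:
            out[s] = 0.0
        else:
            out[s] = float(np.clip(1.0 - (1.0 - u) * m, 0.0, 1.0))
    return out


@dataclass
class PSAResult:
    """Per-iteration incremental outcomes and their summaries."""

    iterations: pd.DataFrame  # columns: iteration, scenario, delta_qalys, net_<persp>
    thresholds: tuple[float, float] = cea_mod.WTP_THRESHOLDS

    def summary(self) -> pd.DataFrame:
        rows = []
        for (scenario,), grp in self.iterations.groupby(["scenario"]):
            for p in PERSPECTIVES:
                net = grp[f"net_{p}"].to_numpy()
                dq = grp["delta_qalys"].to_numpy()
                saving = (net < 0) & (dq > 0)
                row = {
                    "scenario": scenario, "perspective": p,
                    "n_iter": len(grp),
                    "median_delta_qalys": float(np.median(dq)),
                    "median_net_cost": float(np.median(net)),
                    "net_cost_p2.5": float(np.percentile(net, 2.5)),
                    "net_cost_p97.5": float(np.percentile(net, 97.5)),
                    "frac_cost_saving": float(saving.mean()),
                }
                for thr in self.thresholds:
                    below = saving | ((dq > 0) & (net / np.where(dq == 0, np.nan, dq)
                                                  < thr))
                    row[f"frac_icer_below_{int(thr)}"] = float(
                        np.nan_to_num(below, nan=0.0).mean())
                rows.append(row)
        return pd.DataFrame(rows)

    def ce_plane(self, perspective: str = "societal") -> pd.DataFrame:
        """Cost-effectiveness plane points: (delta QALYs, delta cost)."""
        if perspective not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {perspective!r}")
        return self.iterations[["iteration", "scenario", "delta_qalys",
                                f"net_{perspective}"]].rename(
            columns={f"net_{perspective}": "delta_cost"})


def run_psa(population: pd.DataFrame, scenarios: dict, components: pd.DataFrame,
            rr_table: pd.DataFrame, mediated, junk_profile: pd.DataFrame,
            engine_params: EngineParams, cost_inputs: CostInputs,
            horizon: tuple[str, int] = ("5", 5), n_iter: int = 1000,
            seed: int = 0,
            registry: list[ParameterDistribution] | None = None,
            expansion: float | None = None) -> PSAResult:
    """Run the PSA on a fixed population with parameter redraws per iteration.

    The engine's event draws are keyed by a fixed seed, shared by the base
    case and every scenario in every iteration (common random numbers), so
    per-iteration incremental outcomes reflect parameter uncertainty rather
    than between-arm Monte Carlo noise.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if registry is None:
        registry = default_registry()
    label, years = horizon
    horizon_key = "lifetime" if label == "lifetime" else int(label)
    if expansion is None:
        expansion = cost_inputs.participants_adults / len(population)

    engine_seed = int(seed) % (2 ** 31)
    rows = []
    for it in range(n_iter):
        rng = np.random.default_rng([int(seed), 7, it])
        draws = draw_parameter_set(registry, rng)
        try:
            rows.extend(_one_iteration(
                it, draws, population, scenarios, components, rr_table, mediated,
                junk_profile, engine_params, cost_inputs, label, horizon_key,
                years, expansion, engine_seed))
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"PSA iteration {it} failed with overrides {draws}") from exc
    return PSAResult(iterations=pd.DataFrame(rows))


def _one_iteration(it, draws, population, scenarios, components, rr_table,
                   mediated, junk_profile, engine_params, cost_inputs,
                   label, horizon_key, years, expansion, engine_seed):
    m_eff = draws.get("policy.effect_multiplier", 1.0)
    m_rr = draws.get("dietrisk.log_rr_multiplier", 1.0)
    m_cal = draws.get("engine.calibration_multiplier", 1.0)
    m_admin = draws.get("costs.admin_multiplier", 1.0)
    m_hc = draws.get("costs.healthcare_multiplier", 1.0)
    m_food = draws.get("costs.food_spend_multiplier", 1.0)
    m_disu = draws.get("engine.disutility_multiplier", 1.0)

    params_i = replace(
        engine_params,
        calibration_multiplier=engine_params.calibration_multiplier * m_cal,
        state_utility=_perturbed_utilities(engine_params, m_disu))
    costs_i = _scaled_state_costs(cost_inputs.state_costs, m_hc)
    ci = replace(
        cost_inputs,
        state_costs=costs_i,
        admin_schedule={s: {h: v * m_admin for h, v in sched.items()}
                        for s, sched in cost_inputs.admin_schedule.items()},
        per_capita_food_spend={f: v * m_food
                               for f, v in cost_inputs.per_capita_food_spend.items()})
    rr_i = rr_table.copy()
    rr_i["rr_per_unit"] = np.exp(np.log(rr_table["rr_per_unit"]) * m_rr)

    base_res = simulate(population, RiskModifierSet.identity(len(population)),
                        [horizon_key], params_i, engine_seed, costs_i)
    base_tally = base_res.tallies[label]

    out = []
    baseline_means = {f: float(population[f"diet_{f}"].mean())
                      for f in cost_inputs.per_capita_food_spend}
    for sid, scenario in scenarios.items():
        pct = {f: p * m_eff for f, p in scenario_changes(scenario, components).items()}
        change_set = IntakeChangeSet(pct, baseline_means)
        mods = person_modifiers(population, change_set, rr_i, mediated,
                                junk_profile)
        res = simulate(population, mods, [horizon_key], params_i, engine_seed,
                       costs_i)
        ce = evaluate_cea(scenario, change_set, base_tally, res.tallies[label],
                          label, years, expansion, ci)
        out.append({"iteration": it, "scenario": sid,
                    "delta_qalys": ce.delta_qalys,
                    **{f"net_{p}": ce.net_cost[p] for p in PERSPECTIVES}})
    return out
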