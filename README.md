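# snapsim

Individual-level microsimulation of the health and economic consequences of
food-price policies in SNAP (the US Supplemental Nutrition Assistance
Program), for health-policy modellers and cost-effectiveness analysts.

The package simulates a synthetic population of low-income US adults aged
35–80, applies three policy scenarios to their diets — a 30% fruit & vegetable
(F&V) purchase incentive, the F&V incentive plus removal of sugar-sweetened
beverages (SSBs) from eligible purchases, and a broad 30% incentive/30%
disincentive program across nine food categories ("SNAP-plus") — and follows
each person through an annual-cycle state-transition model of cardiovascular
disease (CVD) and type 2 diabetes to estimate events averted, quality-adjusted
life years (QALYs) gained, costs, and incremental cost-effectiveness ratios
(ICERs) at 5-, 10-, 20-year and lifetime horizons.

## Model core

**Policy → diet.** A price instrument changes overall intake of food *f* by

&nbsp;&nbsp;Δ*f* = price response × SNAP-venue share × SNAP-dollar share × (1 − spend shift),

the intake response to a 30% price change attenuated by where the food is
bought, how it is paid for, and substitution toward non-SNAP dollars. A
purchase restriction removes the SNAP-dollar share of intake, less the
fraction shifted to other dollars.

**Diet → risk.** Each food×outcome association is a log-linear dose–response:
RR(Δ) = exp(ln RR₁ · Δ/unit), with the log-RR attenuated linearly per decade
of age. Junk food acts through nine joint associations with other dietary
components; SSBs act both directly and through BMI (kg/m² per serving/day by
age and adiposity stratum); sodium shifts systolic blood pressure.

**Risk → outcomes.** Annual CVD risk comes from the published sex-specific
Framingham general-CVD function, converted to an annual probability
p₁ = 1 − (1 − p₁₀)^(1/10), scaled by a calibration multiplier and the
scenario's per-person RR modifiers. Competing risks are resolved by sequential
conditional draws each cycle (non-CVD death, then a typed and possibly fatal
CVD event, then diabetes onset). Scenarios are compared against the base case
with common random numbers, so incremental outcomes carry no between-arm Monte
Carlo noise. Costs (2017 USD) and QALYs are discounted at 3%/year; ICER =
Δcost/ΔQALY, evaluated from societal and two government-affordability
perspectives against $50,000 and $150,000/QALY thresholds.

See `docs/methods.md` for assumptions, parameter provenance, and limitations.

## Worked example

```python
from snapsim import *
from snapsim.population import NATIONAL_ADULTS
from snapsim.policy import scenario_changes, IntakeChangeSet

pop = generate_population(PopulationConfig(size=100_000, seed=12345))
components = load_effect_components()
scenarios = default_scenarios()
rr = load_rr_table(); mediated = load_mediated_spec(); junk = load_junk_food_profile()
params, costs = EngineParams(), CostInputs()
expansion = NATIONAL_ADULTS / len(pop)   # scale to 14.5M represented adults

base = simulate(pop, RiskModifierSet.identity(len(pop)),
                [5, "lifetime"], params, seed=2018, costs=costs.state_costs)

scen = scenarios["snap_plus"]
pct = scenario_changes(scen, components)
change = IntakeChangeSet(pct, {f: float(pop[f"diet_{f}"].mean())
                               for f in costs.per_capita_food_spend})
mods = person_modifiers(pop, change, rr, mediated, junk)
res = simulate(pop, mods, [5, "lifetime"], params, seed=2018,
               costs=costs.state_costs)

for label, years in (("5", 5), ("lifetime", 66)):
    ce = evaluate_cea(scen, change, base.tallies[label], res.tallies[label],
                      label, years, expansion, costs)
    print(f"{label:>8}: CVD events averted {ce.events_averted:>9,.0f}  "
          f"QALYs gained {ce.delta_qalys:>9,.0f}  "
          f"societal net cost ${ce.net_cost['societal']/1e9:+.2f}B  "
          f"ICER (all participants): {ce.icer['govt_all']}")
```

Output:

```
       5: CVD events averted    96,530  QALYs gained    76,216  societal net cost $-4.11B  ICER (all participants): cost_saving
lifetime: CVD events averted   961,372  QALYs gained 1,779,923  societal net cost $-29.75B  ICER (all participants): cost_saving
```

SNAP-plus averts roughly 97,000 CVD events among the 14.5 million represented
adults in its first 5 years and about 960,000 over their lifetimes. The
societal net cost (administrative costs minus healthcare savings) is negative
— the program saves money while gaining QALYs — and because the disincentives
on SSBs, junk food, and processed meat raise more revenue than the incentives
cost, it is cost-saving even from the broadest government-affordability
perspective.

The same analysis is available from the shell:

```sh
snapsim simulate --size 100000 --seed 2018 --out results/
snapsim psa --n-iter 100 --pop-size 20000 --out results/
snapsim report --config run.yaml
```

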