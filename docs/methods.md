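# Methods

## Scope and model structure

`snapsim` estimates the cardiometabolic health effects and cost-effectiveness
of three food-price policies in SNAP relative to current policy. The causal
chain is: price instrument → change in food intake → change in disease risk
(relative risks and risk-factor shifts) → annual-cycle individual
state-transition simulation of CVD and type 2 diabetes → discounted QALYs and
costs → incremental cost-effectiveness by perspective and horizon.

Health states are disease-free (WELL), one-cycle acute states (ACUTE_MI,
ACUTE_STROKE) that resolve to chronic counterparts (POST_MI, POST_STROKE),
chronic angina and resuscitated-cardiac-arrest survivorship, and two absorbing
death states (CVD, non-CVD). Type 2 diabetes is an orthogonal absorbing flag
that feeds the CVD risk score, accrues annual costs, and decrements utility.
A person occupies exactly one health state per cycle; at most one event occurs
per cycle, resolved by sequential conditional draws in the order non-CVD death
→ CVD event → diabetes onset. The cohort is closed: a baseline population of
adults aged 35–80 is followed with no entrants until the horizon, or until
death or age 100 for the lifetime horizon ("open-cohort" horizons of 5/10/20
years are reported for the same closed baseline cohort).

## Synthetic population

The generator replaces restricted survey microdata with a synthetic population
that preserves the structure the simulation actually uses:

* **Categorical marginals** (sex, race/ethnicity, education, income-to-poverty
  band, federal insurance) are independent draws matching published survey
  marginals of adult SNAP participants.
* **Age** is drawn from a piecewise "tilted-uniform" mixture: within each age
  band the density is linear, f(u) = (1 + s·u)/2 on the normalized band, and
  the tilt vector s is solved (bounded SLSQP, done once per configuration) so
  that band probabilities, the overall mean (52.1 y), and the overall SD
  (12.3 y) are all matched simultaneously. A plain uniform-within-band mixture
  cannot reproduce the published SD given the published band percentages.
* **Continuous risk factors** (SBP, total cholesterol, HDL, BMI) are drawn
  through a Gaussian copula with age, using modest default rank correlations
  (SBP–age 0.35, BMI–SBP 0.20, HDL–BMI −0.20) and truncated-normal margins.
  The published source does not report risk-factor distributions for the SNAP
  subsample, so the margins (SBP 127±17 mmHg, TC 199±40 mg/dL, HDL 51±15
  mg/dL, BMI 30±6.5 kg/m²) and baseline prevalences (smoking 30%, diabetes
  25%, with a logistic BMI gradient) are calibration inputs chosen to reflect
  a low-income US adult population.
* **Diet** is nine independent gamma-distributed intakes with means equal to
  the published baseline consumption (fruits 81.3, vegetables 134.8, nuts 5.4,
  whole grains 13.9, fish 20.6, plant oils 18.7, SSBs 414, processed meat
  31.8, junk food 66.5 g/day) and coefficient of variation 1.0 — intakes are
  non-negative and right-skewed, and only means are published. SSB mass↔volume
  uses 29.57 g/fl oz (414 g = 14.0 fl oz).
* **Survey weights** are 1 for synthetic persons; national scale is applied by
  a single expansion factor to 14,537,610 represented adults (42,138,000
  participants × 34.5% aged 35+).

What the generator does **not** emulate: joint dependence between diet and
risk factors or between dietary components, within-person reporting error of
dietary recalls, survey design effects, and secular cohort differences.
Passing tests therefore demonstrate correctness of the mechanism on a
population with the published marginal structure, not replication of results
that depend on the real joint microdata.

## Policy effects

Overall intake change per food: Δ% = price response × SNAP-venue share ×
SNAP-dollar share × (1 − spend shift). The shipped component table uses
venue share 0.88, SNAP-dollar share 0.76, spend shift 0 for incentives and
0.30 for disincentives, with price responses back-solved so that composites
equal the published overall effects (fruits +23.4%, vegetables +19.0% under
the F&V incentive; per-food SNAP-plus composites from the published change
table; SSB restriction −33.2% from a 66.4% SNAP retail share with 50%
substitution). The composites, not the components, are the calibrated ground
truth. Two internal inconsistencies of the published table are preserved
rather than forced: 23.4% × 81.3 = 19.03 g/d (printed 19.1) and
33.2% × 414 = 137.4 g/d (printed 139). Changes apply uniformly (the same Δ%
for every person, acting on that person's own baseline intake), with no lag
from intervention onset.

## Diet–disease effects

Dose–response is log-linear in intake with no thresholds, the standard
comparative-risk-assessment convention. The log-RR attenuates linearly with
age: ln RR(age) = ln RR(ref) · max(0, 1 − a·(age − ref)/10), never crossing 1.
The shipped RR table (per 100 g/d, 10 g/d, or 50 g/d units at reference age
50 with attenuation 0.15/decade) is a calibration input assembled from the
magnitude ranges typical of the meta-analytic CRA literature; fruits and
vegetables deliberately carry **no** diabetes association (no
probable/convincing etiologic evidence), which produces the lifetime
"survival artifact": an F&V-only policy slightly *increases* lifetime diabetes
case counts because averted CVD deaths leave more survivors at risk.

Junk food acts through nine joint associations (shipped profile: negative
associations with fruits, vegetables, nuts, fish, plant oils; positive with
SSBs, processed meat, sodium, and a small positive whole-grain term, so the
composite mixes benefit and harm). SSBs additionally shift BMI (0.05–0.23
kg/m² per serving/day by age and overweight/obesity stratum), applied through
per-kg/m² outcome RRs (CHD 1.06, stroke 1.04, diabetes 1.23) as factors
separate from the direct BMI-independent SSB terms; diabetes incidence itself
uses baseline BMI, so the mediated pathway is not double-counted. Junk-food
sodium (3.5 mg/g) shifts SBP via slopes stratified by age, race, and
hypertension (1–4.8 mmHg per g/day), feeding the risk score directly. Each
food×outcome RR factor is clamped to [0.5, 2.0] per simulated change to guard
against extreme synthetic intake draws.

## Engine parameters

| Parameter | Default | Notes |
|---|---|---|
| Risk score | Framingham general-CVD (2008), untreated-SBP coefficients | published equation; no treatment flag in the population |
| 10-y → annual | p₁ = 1 − (1 − p₁₀)^0.1 | constant-hazard conversion |
| Calibration multiplier | 1.0 | scales annual CVD probability; PSA-perturbed |
| Stroke share of events | 0.35 | calibration input |
| CHD split MI/angina/RCA | 0.55/0.35/0.10 | calibration input |
| Case fatality (<65 / 65+) | MI 0.25/0.40, stroke 0.20/0.35, RCA 0.60/0.70, angina 0.01/0.02 | calibration input |
| Recurrent-event multiplier | 2.0 | CVD hazard in chronic states |
| Diabetes incidence | 0.004/yr at age 50, BMI 27; ×1.03/yr of age, ×1.07/kg/m²; cap 0.05 | calibration input |
| Non-CVD mortality | q(a) = q₃₅·e^{0.085(a−35)}, q₃₅ = 0.0020 (M)/0.0013 (F), cap 0.6 | Gompertz approximation of non-CVD life-table rates |
| Risk-factor trends | SBP +0.35 mmHg/yr, TC +0.40 mg/dL/yr, BMI +0.05/yr | combined age + secular drift |
| Utilities | well 1.00, acute MI 0.80, acute stroke 0.70, post-MI 0.88, post-stroke 0.80, angina/RCA 0.85; −0.0015/yr age decrement (floor 0.40); diabetes ×0.97 | calibration input |
| Healthcare costs (2017 USD) | acute: MI $45k, stroke $42k, RCA $65k, angina $15k; fatal event +$20k; chronic $3.6–6.5k/yr; diabetes $3k/yr | calibration input |
| Discount rate | 3%/yr, costs and QALYs | |

Event-type splits, case fatality, utilities, the diabetes incidence model,
non-CVD mortality, and healthcare state costs are declared calibration inputs:
they are not published at the level of detail the simulation needs, so these
defaults set the *scale* of results while the in-package arithmetic identities
and coupling properties set their *correctness*.

## Costing and cost-effectiveness

Administrative costs are shipped as a direct cumulative discounted schedule
per scenario and horizon ($125–317M). Per-capita SNAP-dollar food spending
(adults: F&V ≈ $202.5/person-year split 45:55, SSBs $260, junk food $235,
processed meat $150, fish $90, oils $60, whole grains $25, nuts $15;
non-adult participants × 0.679) is back-solved so the 5-year discounted F&V
subsidy lands on the published scale (≈ $11.5B for all participants, ≈ $5.0B
for adults). Subsidy outlays scale with post-policy consumption and accrue
only over surviving discounted adult person-years; the non-adult pool is
constant (no mortality is modelled for it, and it never contributes QALYs or
healthcare savings). Restrictions produce no program savings. Perspectives:
societal = admin − healthcare savings; government-affordability adds net food
subsidy cost for adults, or for all participants. ICER = net cost/ΔQALY, with
`cost_saving` (ΔQALY > 0, net cost < 0) and `dominated` (ΔQALY < 0, net
cost > 0) flags, classified exactly at $50,000 and $150,000/QALY.

## Randomness and numerical choices

* One uniform-draw block per (seed, year), independent of scenario: common
  random numbers make base-vs-base increments exactly zero and protective
  scenarios avert a non-negative number of events pathwise.
* Half-cycle correction: persons dying within a cycle accrue 0.5 years at
  their pre-death state's utility; survivors accrue a full year at their
  end-of-cycle state (acute utilities apply in the event year).
* Per-cycle event probability capped at 0.95 (1.0 reachable only via the
  degenerate-parameter test override); 10-year risk computation caps age at 95
  to stay within the score's support.
* PSA percentiles use linear interpolation between order statistics; PSA
  distribution families are lognormal (RR log-scale multiplier), truncated
  normal (policy effect multiplier), gamma (cost multipliers, CV 0.1–0.2), and
  a bounded gamma multiplier on utility *decrements*; all centered on point
  estimates. The PSA holds the population fixed across iterations and redraws
  parameters only, on a reduced population of 20,000 (a scaled-down design
  relative to a million-person production run; the engine itself handles
  10⁵–10⁶ persons).
* Default problem sizes: 100,000 persons for point-estimate runs, 50,000 for
  the Markov-oracle validation, 20,000 × 100 iterations for the PSA.

## Validation strategy

1. Arithmetic identities of the published tables (policy-effect products,
   guideline fractions, net-savings and ICER recomputation) are asserted
   exactly or to printed precision.
2. A homogeneous constant-hazard cohort is compared against an independent
   closed-form Markov oracle (`advance_cohort_markov`) within 3 Monte Carlo
   SEs for mean events and QALYs.
3. Structural properties are tested directly: identity modifiers give exactly
   zero incrementals, log-additivity of combined RRs, age attenuation
   monotonicity, perspective ordering, determinism of seeded runs at byte
   level.

## Limitations

Results at national scale depend on calibration inputs (risk-factor
distributions, event splits, utilities, unit costs) whose true values are in
unpublished supplements; the package reproduces the mechanism and in-paper
arithmetic, and its absolute event/QALY/cost totals agree with the published
ones in ordering and magnitude but not to printed precision. No entrant
dynamics, no cancer or child/young-adult health outcomes, no indirect or
productivity costs, no heterogeneity in policy response across persons, and no
demand-system substitution beyond the spend-shift factors.
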