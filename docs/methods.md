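# Methods

## Model structure

The model is a deterministic Markov cohort recursion over five health states
— NYHA classes I–IV and an absorbing death state — with 3-month cycles and a
13-year horizon (52 cycles), entered at mean age 67.3 with initial NYHA
distribution (0, 0.590, 0.397, 0.013). Two strategies are compared: standard
HFrEF treatment (ACEI/ARB, beta-blocker, MRA) and standard treatment plus
vericiguat titrated 2.5 → 5 → 10 mg daily.

Within a cycle, events are applied to each living state in a fixed order:

1. **Death.** Arm-specific cardiovascular mortality (3-month probability)
   plus non-cardiovascular background mortality from age brackets
   (68–70: 0.244%, 71–75: 0.312%, 76–80: 0.450% per cycle). The two
   probabilities combine additively — they are small (≪ 1) and tabulated
   separately — with a clamp at 1 and a logged warning if ever exceeded.
   Deaths are split proportionally by cause. Ages below the first bracket
   use the first rate, ages above the last use the last.
2. **Hospitalization.** Survivors are admitted with the arm's 3-month
   probability; each admitted fraction experiences at most one same-cycle
   readmission with the arm's conditional readmission probability, in the
   same NYHA class. Every admission (first or readmission) incurs the
   NYHA-specific admission cost and disutility. Event probabilities are
   NYHA-independent within an arm (only arm-level rates are published);
   admission costs and disutilities are NYHA-specific.
3. **Transition.** Survivors redistribute across NYHA classes by the shared
   4×4 row-stochastic matrix. Death is absorbing.

The ordering is a reproducibility convention, not an empirical claim; with
state-independent event probabilities it does not affect totals.

## Accounting conventions

* **Half-cycle correction.** State-occupancy rewards — drug cost, state
  utility, life-years — accrue on the trapezoidal mean of cycle-start and
  cycle-end membership. One-off event rewards (admission costs,
  disutilities) accrue at full weight in the cycle they occur. The dead
  accrue nothing.
* **Discounting.** Costs and QALYs are discounted at 5%/year with factor
  (1.05)^(−(k−1)/4) for cycle k; the first cycle is undiscounted.
  Life-years are reported undiscounted.
* **Drug costs.** Standard arm: 994.93 CNY/cycle (a 2017 estimate of
  906 CNY carried through the 2018–2022 inflation chain 1.043 × 1.024 ×
  1.018 × 1.004 × 1.006). Vericiguat arm: the titration schedule prices the
  first cycle as one 2.5 mg box (238.84 CNY) plus nine 5 mg boxes (406 CNY)
  = 3892.84 CNY, and maintenance cycles as twelve 5 mg boxes = 4872 CNY, on
  top of the standard regimen.
* **Utilities** are 3-month increments (annual utility weight ÷ 4):
  0.2138 / 0.1865 / 0.1485 / 0.1408 for NYHA I–IV; disutility per admission
  −0.01 / −0.02 / −0.03 / −0.07. Death has utility 0.
* **Rounding.** Full floating precision everywhere; 2-decimal rounding only
  in reports and exported tables.

## Outcomes and decision rules

Incremental cost ΔC and effect ΔE give ICUR = ΔC/ΔE when ΔE ≠ 0; sign
disagreements set a dominance flag instead of a ratio. The intervention is
cost-effective iff it dominates or ΔE > 0 with ICUR ≤ WTP; this is
algebraically equivalent to a positive incremental net monetary benefit
(property-tested).

The value-based price threshold bisects the 5 mg box price on (0, current
price], rebuilding the titrated cycle costs at each candidate (2.5 mg box
repriced proportionally; repricing the titrated first cycle is the default
and is configurable) and re-running the full model. Total cost is affine in
the box price and QALYs are unaffected, so the ICUR is strictly increasing
in price and bisection (absolute tolerance 0.01 CNY) is exact.

## Sensitivity analyses

**One-way.** Fifteen parameters carry published ranges: the two per-cycle
medication costs (±10%), four admission costs (±10%), the discount rate
(0–8%), four utilities (literature ranges) and the four event probabilities
(±5%). Each is set to its bounds with all others at base and the ICUR
recorded; entries are reported in descending spread (tornado) order. The
basic-regimen cost is varied in the standard arm alone, matching the
published analysis' behaviour; the vericiguat cycle cost is varied as a
multiplier so the titrated first cycle keeps its ratio to maintenance
cycles.

**Probabilistic.** Each iteration draws: event probabilities and utilities
from Beta(100p, 100(1−p)) — the pseudo-count-100 parameterisation of the
source tables; costs from Gamma distributions parameterised by mean/SD via
method of moments; the vericiguat cycle cost through a single Gamma
multiplier shared by first and maintenance cycles; transition rows from
Dirichlet(row × 100). The Dirichlet pseudo-count is not published; 100
mirrors the Beta convention and is the dominant unverifiable assumption of
the probabilistic analysis. Utility draws are clipped at the 0.25 per-cycle
ceiling (perfect health); structural zeros of the transition matrix stay
zero. Readmission probabilities, background mortality and disutilities have
no published uncertainty and stay fixed. Parameters are drawn independently
(no correlation structure is published). One NumPy generator per iteration
is spawned deterministically from the master seed, so results are exactly
reproducible and CSV outputs byte-identical for a given seed. The CEAC is
evaluated on a configurable WTP grid, default 0–500,000 CNY in steps of
5,000. The NYHA IV admission cost deliberately carries two values: the
deterministic base case uses the printed base (46,659.46 CNY) while
probabilistic draws use the printed Gamma (mean 42,488.95, SD 2,380.58),
reproducing an internal inconsistency of the source tables.

## Synthetic scenarios and the microsimulation oracle

`ScenarioSpec` draws random valid configurations with the same statistical
structure as the base case: Dirichlet transition rows, uniform event
probabilities, Gamma costs and Beta utilities within configurable ranges.
The defaults are the base-case values themselves, so zero-width ranges
regenerate the bundled scenario; `ScenarioSpec.randomized` widens every
range to values plausible for a chronic-HF population (e.g. CV mortality
1.5–5% per cycle, admission probability 5–15%) for property testing.

The microsimulation oracle replays the identical event logic per patient
(Bernoulli death, admission and readmission draws, categorical transitions)
and credits occupancy rewards half at the cycle-start state and half at the
cycle-end state, which equals the cohort engine's trapezoid in expectation.
It emulates no patient-level heterogeneity beyond event randomness — its
sole purpose is to validate the cohort engine, which the test suite does at
n = 20,000 patients (cohort totals within 3 Monte-Carlo standard errors on
the bundled scenario and on random scenarios). Agreement between the two
routes shows the recursion and its accounting are implemented correctly; it
does not validate the inputs against real-world Chinese HFrEF data.

## Known reproduction limits

The bundled inputs reproduce the published input arithmetic exactly
(994.93; 3892.84; 4872) and the published probabilistic result within
Monte-Carlo error (~42–44% vs 41.7% at WTP 257,100). The deterministic
headline outputs, however, are **not** fully recoverable from the published
inputs under any coherent convention, and this package does not force them:

* The rebuilt incremental cost (102,508 CNY) matches the published
  103,797.76 within 1.3%, and the per-arm discounted occupancies implied by
  the published one-way cost rows match the rebuild to ~1%.
* The published incremental QALY gain (0.1294 at full precision) requires a
  between-arm survival gap of ≈ 0.68 discounted cycles, while the published
  CV-mortality gap (0.0233 vs 0.0256 per cycle) forces ≥ 0.90 cycles in any
  model where the arms differ only through the tabulated inputs. The
  rebuild obtains ΔE = 0.167, hence ICUR ≈ 613,000 rather than ≈ 802,000
  CNY/QALY, and price thresholds of ≈ 184 / 77 CNY rather than 145.8 / 65.7.
* The published tables are internally inconsistent on exactly this
  quantity: their utility sensitivity rows imply a total occupancy gap of
  0.68 cycles while their cost sensitivity rows imply 0.93. Substituting
  the published ΔE into the rebuilt cost structure yields thresholds of
  147.8 / 65.1 CNY, confirming the discrepancy is confined to the survival
  gap.

The corresponding comparisons in `tests/test_acceptance.py` are asserted at
the published values and fail honestly rather than being tuned. All
structural invariants, the input arithmetic, the oracle equivalence and the
probabilistic comparison pass.

## Limitations

Adverse events, treatment discontinuation, adherence and indirect costs are
outside the model, as in the source analysis. Event probabilities are
NYHA-independent within an arm; background mortality beyond age 80 reuses
the 76–80 bracket. The model is a cohort expectation — individual-level
variance is available only through the oracle.
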