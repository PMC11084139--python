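# hfcua

Markov cohort cost-utility analysis of add-on **vericiguat** versus standard
treatment for chronic heart failure with reduced ejection fraction (HFrEF),
from the Chinese healthcare payer perspective.

`hfcua` reimplements a published TreeAge-style decision model as a tested,
reusable Python library: a five-state cohort engine (NYHA I–IV plus death,
3-month cycles over a 13-year horizon), incremental cost-utility outcomes,
deterministic and probabilistic sensitivity analyses, and value-based price
threshold solving. It is aimed at health-economics researchers who want to
inspect, rerun or perturb every assumption of the analysis rather than trust
a black-box model.

## The model

A cohort enters at mean age 67.3 with NYHA distribution (0%, 59.0%, 39.7%,
1.3%). Each 3-month cycle layers three event stages on the living states:

1. **Death** — arm-specific cardiovascular mortality plus age-bracketed
   non-cardiovascular background mortality, combined additively;
2. **Hospitalization** — survivors are admitted with an arm-specific
   probability; an admission can be followed by one same-cycle readmission
   (the post-discharge "vulnerable period"), each admission incurring a
   NYHA-specific cost and disutility;
3. **NYHA transition** — survivors move between classes by a shared
   row-stochastic transition matrix.

Per cycle, state-occupancy rewards (drug cost, utility, life-years) are
half-cycle corrected (trapezoidal mean of cycle-start and cycle-end
membership); event rewards enter at full weight. Costs *C* and QALYs *E* are
discounted at 5% per year. The two arms are compared by the incremental
cost-utility ratio ICUR = ΔC/ΔE against willingness-to-pay thresholds of
1x and 3x China's 2022 GDP per capita (85,700 / 257,100 CNY per QALY), and
equivalently by net monetary benefit NMB = WTP·E − C.

Parameter uncertainty follows the published parameterisation: Beta
(pseudo-count 100) for probabilities and utilities, Gamma (mean/SD) for
costs, Dirichlet for transition rows. All base-case inputs (2022 CNY) ship
as a bundled, validated YAML fixture (`hfcua.base_case()`).

## Worked example

```sh
$ hfcua base-case --out out/
 treatment  total_cost_cny  qalys  mean_life_years  incremental_cost_cny  incremental_qaly  icur_cny_per_qaly
vericiguat       250318.47   3.87             7.06             102507.99              0.17          613487.24
  standard       147810.48   3.70             6.73                   NaN               NaN                NaN
ICUR: 613487.24 CNY/QALY at WTP 257100 -> not cost-effective
```

Adding vericiguat buys 0.17 QALYs for an extra 102,508 CNY, i.e. about
613,000 CNY per QALY — far above the 3x-GDP threshold, so the add-on is not
cost-effective at its 2022 list price (406 CNY per 14-tablet 5 mg box).

```sh
$ hfcua sensitivity --mode psa --n-iterations 1000 --seed 1 --out out/
P(cost-effective at WTP 257100) = 0.436 (1000 iterations, seed 1)

$ hfcua price-threshold --wtp 257100 --out out/
threshold 5 mg box price at WTP 257100: 184.0 CNY
```

The probabilistic analysis (Beta/Gamma/Dirichlet draws, 1000 iterations)
puts the probability of cost-effectiveness at about 44% — the huge sampling
spread of the two CV-mortality Betas means the *sign* of the QALY gain is
itself uncertain. Bisection on the box price shows the 5 mg box would have
to fall to roughly 184 CNY (2.5 mg box repriced proportionally) before the
ICUR meets the 3x-GDP threshold.

The same computations are available as library calls (`run_cua`, `run_psa`,
`one_way_sa`, `price_threshold`), and `hfcua sensitivity --mode oneway`
writes the tornado table. The `hfcua.synthetic` module generates random
valid scenarios and provides an individual-level microsimulation oracle that
replays the engine's event logic patient-by-patient; the test suite uses it
to validate every cohort total to within Monte-Carlo error.

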