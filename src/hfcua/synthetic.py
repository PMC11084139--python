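"""Random scenario generation and an individual-level microsimulation oracle.

The generator produces random but valid two-arm configurations with the same
statistical structure as the bundled base case (row-stochastic Dirichlet
transition matrices, Beta-style probabilities and utilities, Gamma-style
costs).  Its defaults are the published base-case values, so a spec with
zero-width ranges reproduces the bundled scenario; :meth:`ScenarioSpec.randomized`
widens every range for property testing.

The microsimulation oracle replays the cohort engine's event logic patient by
patient — death, hospitalization, readmission, then NYHA transition, in that
order — and applies the half-cycle correction as an occupancy weight of 1/2
at each cycle boundary, so its per-patient expectations equal the cohort
totals exactly.  Its only purpose is to validate the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import (
    N_LIVING,
    Arm,
    BackgroundMortality,
    CostInputs,
    EventRates,
    HealthState,
    ModelConfig,
    ParamDistribution,
    TransitionMatrix,
    UtilityInputs,
    ValidationError,
    VericiguatPricing,
    base_case,
    beta_from_percent,
    gamma_from_mean_sd,
)
from .engine import discount_factor

__all__ = ["ScenarioSpec", "MicrosimResult", "generate_scenario",
           "microsim_oracle"]

Range = tuple[float, float]

_BASE_HOSP = (7624.03, 28657.14, 53589.71, 46659.46)
_BASE_UTIL = (0.2138, 0.1865, 0.1485, 0.1408)
_BASE_DISUTIL = (-0.01, -0.02, -0.03, -0.07)
_BOX_RATIO_2_5_TO_5 = 238.84 / 406.0


def _deg(x: float) -> Range:
    return (x, x)


@dataclass(frozen=True)
class ScenarioSpec:
    """Ranges from which a random scenario is drawn.

    Every scalar has a (low, high) range; a zero-width range pins the value.
    The defaults are the published base case.  ``transition_concentration``
    and ``init_concentration`` are Dirichlet pseudo-counts applied to the
    base rows; ``None`` keeps the base values unchanged.
    """

    seed: int = 0
    horizon_years: float = 13.0
    cycle_length_years: float = 0.25
    baseline_age: float = 67.3
    discount_range: Range = _deg(0.05)
    wtp_per_qaly: float = 257100.0
    comparator_p_cv_range: Range = _deg(0.0256)
    comparator_p_hosp_range: Range = _deg(0.0929)
    comparator_p_readmit_range: Range = _deg(0.7885)
    intervention_p_cv_range: Range = _deg(0.0233)
    intervention_p_hosp_range: Range = _deg(0.0849)
    intervention_p_readmit_range: Range = _deg(0.7699)
    basic_cost_range: Range = _deg(994.93)
    addon_later_cost_range: Range = _deg(5866.93)  # combined basic + add-on
    hosp_cost_ranges: tuple[Range, ...] = tuple(_deg(c) for c in _BASE_HOSP)
    utility_ranges: tuple[Range, ...] = tuple(_deg(u) for u in _BASE_UTIL)
    disutility_ranges: tuple[Range, ...] = tuple(_deg(d) for d in _BASE_DISUTIL)
    noncv_scale_range: Range = _deg(1.0)
    transition_concentration: float | None = None
    init_concentration: float | None = None

    @classmethod
    def randomized(cls, seed: int) -> "ScenarioSpec":
        """A spec with wide but realistic ranges for property testing."""
        return cls(
            seed=seed,
            discount_range=(0.0, 0.08),
            comparator_p_cv_range=(0.015, 0.05),
            comparator_p_hosp_range=(0.05, 0.15),
            comparator_p_readmit_range=(0.4, 0.9),
            intervention_p_cv_range=(0.015, 0.05),
            intervention_p_hosp_range=(0.05, 0.15),
            intervention_p_readmit_range=(0.4, 0.9),
            basic_cost_range=(500.0, 2000.0),
            addon_later_cost_range=(3000.0, 9000.0),
            hosp_cost_ranges=tuple((0.6 * c, 1.4 * c) for c in _BASE_HOSP),
            utility_ranges=tuple((max(0.0, u - 0.03), min(0.25, u + 0.03))
                                 for u in _BASE_UTIL),
            disutility_ranges=tuple((d * 1.5, d * 0.5) for d in _BASE_DISUTIL),
            noncv_scale_range=(0.5, 2.0),
            transition_concentration=100.0,
            init_concentration=100.0,
        )


def _uniform(rng: np.random.Generator, r: Range) -> float:
    lo, hi = r
    if hi < lo:
        raise ValidationError(f"infeasible range ({lo}, {hi})")
    return lo if hi == lo else float(rng.uniform(lo, hi))


def _beta_in(rng: np.random.Generator, r: Range) -> float:
    lo, hi = r
    if hi < lo:
        raise ValidationError(f"infeasible range ({lo}, {hi})")
    return lo if hi == lo else lo + (hi - lo) * float(rng.beta(2.0, 2.0))


def _gamma_in(rng: np.random.Generator, r: Range) -> float:
    """Gamma draw with mean at the range midpoint, clipped into the range."""
    lo, hi = r
    if hi < lo:
        raise ValidationError(f"infeasible range ({lo}, {hi})")
    if hi == lo:
        return lo
    mean = 0.5 * (lo + hi)
    sd = (hi - lo) / 4.0
    shape = (mean / sd) ** 2
    return float(np.clip(rng.gamma(shape, sd * sd / mean), lo, hi))


def _dirichlet_rows(rng: np.random.Generator, base: np.ndarray,
                    concentration: float) -> np.ndarray:
    out = np.zeros_like(base)
    for i, row in enumerate(np.atleast_2d(base)):
        pos = row > 0
        out_row = np.zeros_like(row)
        out_row[pos] = rng.dirichlet(row[pos] * concentration)
        out[i] = out_row
    return out


def _build_distributions(arms: dict[str, Arm], utilities: UtilityInputs,
                         transition: TransitionMatrix,
                         discount: float) -> dict[str, ParamDistribution]:
    """Uncertainty structure mirroring the base case's parameterisation."""
    dists: dict[str, ParamDistribution] = {}
    for name, arm in arms.items():
        ev = arm.events
        dists[f"{name}.p_cv_death"] = beta_from_percent(
            ev.p_cv_death * 100, low=0.95 * ev.p_cv_death,
            high=1.05 * ev.p_cv_death)
        dists[f"{name}.p_hosp"] = beta_from_percent(
            ev.p_hosp * 100, low=0.95 * ev.p_hosp, high=1.05 * ev.p_hosp)
    comp, interv = arms[list(arms)[0]], arms[list(arms)[1]]
    dists["cost.standard_cycle"] = gamma_from_mean_sd(
        comp.costs.c_standard_cycle, 0.05 * comp.costs.c_standard_cycle,
        low=0.9 * comp.costs.c_standard_cycle,
        high=1.1 * comp.costs.c_standard_cycle)
    dists["cost.vericiguat_cycle"] = gamma_from_mean_sd(
        interv.costs.c_arm_later_cycle, 0.05 * interv.costs.c_arm_later_cycle,
        low=0.9 * interv.costs.c_arm_later_cycle,
        high=1.1 * interv.costs.c_arm_later_cycle)
    for i, c in enumerate(comp.costs.c_hosp_by_state):
        dists[f"cost.hosp_nyha{i + 1}"] = gamma_from_mean_sd(
            c, 0.05 * c, low=0.9 * c, high=1.1 * c)
    for i, u in enumerate(utilities.u_by_state):
        dists[f"utility.nyha{i + 1}"] = beta_from_percent(
            u * 100, low=max(0.0, 0.95 * u), high=min(0.25, 1.05 * u))
    dists["discount_rate"] = ParamDistribution(
        "fixed", {"value": discount}, low=0.0, high=0.08)
    for i, row in enumerate(transition.probs):
        dists[f"transition.nyha{i + 1}"] = ParamDistribution(
            "dirichlet", {"concentration": (row * 100).tolist()})
    return dists


def generate_scenario(spec: ScenarioSpec) -> ModelConfig:
    """Draw one valid random configuration; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    template = base_case()

    transition = template.transition
    if spec.transition_concentration is not None:
        transition = TransitionMatrix(_dirichlet_rows(
            rng, template.transition.probs, spec.transition_concentration))
    init = template.initial_distribution
    if spec.init_concentration is not None:
        init = _dirichlet_rows(rng, init[None, :],
                               spec.init_concentration)[0]

    events = {}
    for arm_key in ("comparator", "intervention"):
        events[arm_key] = EventRates(
            p_cv_death=_uniform(rng, getattr(spec, f"{arm_key}_p_cv_range")),
            p_hosp=_uniform(rng, getattr(spec, f"{arm_key}_p_hosp_range")),
            p_readmit=_uniform(rng, getattr(spec, f"{arm_key}_p_readmit_range")),
        )
    basic = _gamma_in(rng, spec.basic_cost_range)
    addon_later = _gamma_in(rng, spec.addon_later_cost_range)
    if addon_later < basic:
        addon_later = basic
    hosp = np.array([_gamma_in(rng, r) for r in spec.hosp_cost_ranges])
    utils = np.array([_beta_in(rng, r) for r in spec.utility_ranges])
    disutils = np.array([_uniform(rng, r) for r in spec.disutility_ranges])
    noncv_scale = _uniform(rng, spec.noncv_scale_range)
    discount = _uniform(rng, spec.discount_range)

    # titration structure ties the first add-on cycle to the maintenance
    # price: one 2.5 mg box plus nine 5 mg boxes vs twelve 5 mg boxes
    box5 = (addon_later - basic) / 12.0
    pricing = VericiguatPricing(box_5mg_cny=box5 if box5 > 0 else 406.0,
                                box_2_5mg_cny=_BOX_RATIO_2_5_TO_5 * (box5 if box5 > 0 else 406.0))
    first_drug, later_drug = pricing.cycle_costs()

    inflation = template.arm(template.arm_names[0]).costs.inflation_factors
    arms = {
        "standard": Arm("standard", events["comparator"], CostInputs(
            c_standard_cycle=basic, c_arm_first_cycle=basic,
            c_arm_later_cycle=basic, c_hosp_by_state=hosp,
            inflation_factors=inflation)),
        "vericiguat": Arm("vericiguat", events["intervention"], CostInputs(
            c_standard_cycle=basic, c_arm_first_cycle=basic + first_drug,
            c_arm_later_cycle=basic + later_drug, c_hosp_by_state=hosp,
            inflation_factors=inflation)),
    }
    utilities = UtilityInputs(u_by_state=utils, disutility_by_state=disutils)
    background = BackgroundMortality(tuple(
        (lo, hi, min(1.0, p * noncv_scale))
        for lo, hi, p in template.background_mortality.brackets))
    return ModelConfig(
        name=f"synthetic_seed{spec.seed}",
        horizon_years=spec.horizon_years,
        cycle_length_years=spec.cycle_length_years,
        baseline_age=spec.baseline_age,
        initial_distribution=init,
        discount_rate_annual=discount,
        wtp_per_qaly=spec.wtp_per_qaly,
        transition=transition,
        background_mortality=background,
        utilities=utilities,
        arms=arms,
        distributions=_build_distributions(arms, utilities, transition,
                                           discount),
        pricing=pricing,
    )


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrosimResult:
    """Per-patient discounted cost, discounted QALYs and life-years."""

    arm_name: str
    n_patients: int
    cost: np.ndarray
    qalys: np.ndarray
    life_years: np.ndarray
    seed: int = field(default=0)

    def _mean_se(self, x: np.ndarray) -> tuple[float, float]:
        se = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
        return float(x.mean()), se

    @property
    def mean_cost(self) -> tuple[float, float]:
        return self._mean_se(self.cost)

    @property
    def mean_qalys(self) -> tuple[float, float]:
        return self._mean_se(self.qalys)

    @property
    def mean_life_years(self) -> tuple[float, float]:
        return self._mean_se(self.life_years)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "patient": np.arange(1, self.n_patients + 1),
            "cost": self.cost, "qalys": self.qalys,
            "life_years": self.life_years,
        })


def microsim_oracle(config: ModelConfig, arm_name: str, n_patients: int,
                    seed: int) -> MicrosimResult:
    """Simulate individual trajectories with the engine's event logic.

    Per cycle and patient: a death draw (CV plus background, additive and
    clamped at 1), a hospitalization draw among survivors, a readmission draw
    among the hospitalized, then a categorical NYHA transition.  Occupancy
    rewards (drug cost, utility, life-years) are credited half at the cycle
    start state and half at the cycle end state, which reproduces the cohort
    engine's trapezoidal half-cycle correction in expectation; admission
    costs and disutilities are credited in full in the cycle they occur.
    """
    if n_patients < 1:
        raise ValidationError(f"n_patients must be >= 1, got {n_patients}")
    arm = config.arm(arm_name)
    rng = np.random.default_rng(seed)
    n_cycles = config.n_cycles
    dt = config.cycle_length_years
    u = np.append(config.utilities.u_by_state, 0.0)       # DEAD has utility 0
    du = config.utilities.disutility_by_state
    c_hosp = arm.costs.c_hosp_by_state
    cum_t = np.cumsum(config.transition.probs, axis=1)

    state = rng.choice(N_LIVING, size=n_patients,
                       p=config.initial_distribution)
    cost = np.zeros(n_patients)
    qalys = np.zeros(n_patients)
    life_years = np.zeros(n_patients)

    for k in range(1, n_cycles + 1):
        age = config.baseline_age + dt * (k - 1)
        p_death = min(1.0, arm.events.p_cv_death
                      + config.background_mortality.rate_at(age))
        alive_start = state < N_LIVING
        dies = alive_start & (rng.random(n_patients) < p_death)
        survives = alive_start & ~dies
        hosp = survives & (rng.random(n_patients) < arm.events.p_hosp)
        readmit = hosp & (rng.random(n_patients) < arm.events.p_readmit)

        # categorical transition for survivors; the dying move to DEAD
        r = rng.random(n_patients)
        new_state = np.full(n_patients, int(HealthState.DEAD))
        if survives.any():
            rows = cum_t[state[survives]]
            new_state[survives] = (r[survives, None] > rows).sum(axis=1)

        df = discount_factor(k, config.discount_rate_annual, dt)
        occupancy = 0.5 * alive_start + 0.5 * (new_state < N_LIVING)
        drug = arm.costs.drug_cost(k) * occupancy
        u_start = np.where(alive_start, u[np.minimum(state, N_LIVING)], 0.0)
        u_end = u[np.minimum(new_state, N_LIVING)]
        gain = 0.5 * u_start + 0.5 * u_end
        adm_cost = np.zeros(n_patients)
        adm_dis = np.zeros(n_patients)
        for mask in (hosp, readmit):
            if mask.any():
                adm_cost[mask] += c_hosp[state[mask]]
                adm_dis[mask] += du[state[mask]]
        cost += df * (drug + adm_cost)
        qalys += df * (gain + adm_dis)
        life_years += dt * occupancy
        state = new_state

    return MicrosimResult(arm_name=arm_name, n_patients=n_patients,
                          cost=cost, qalys=qalys, life_years=life_years,
                          seed=seed)
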