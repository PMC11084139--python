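"""Deterministic Markov cohort recursion with layered events and discounting.

Each 3-month cycle applies, in order: death (cardiovascular plus age-bracketed
non-cardiovascular background mortality, combined additively), then heart-
failure hospitalization of the survivors (with a possible same-cycle
readmission), then redistribution of survivors across NYHA classes by the
shared transition matrix.  Death is absorbing.

State-occupancy quantities (drug cost, state utility, life-years) are
half-cycle corrected: they are accrued on the trapezoidal mean of cycle-start
and cycle-end membership.  One-off event quantities (admission costs and
disutilities) enter at full weight in the cycle they occur.  Costs and QALYs
are discounted at the annual rate with the first cycle undiscounted;
life-years are reported undiscounted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .config import (
    N_LIVING,
    BackgroundMortality,
    EventRates,
    HealthState,
    ModelConfig,
    TransitionMatrix,
)

__all__ = [
    "discount_factor",
    "step_cycle",
    "run_cohort",
    "CycleEvents",
    "CycleLedger",
    "CohortTrace",
]

log = logging.getLogger(__name__)


def discount_factor(cycle_index: int, annual_rate: float,
                    cycle_length_years: float) -> float:
    """Discount multiplier for a cycle; cycle 1 is undiscounted.

    ``(1 + r)^(-(k - 1) * cycle_length)`` for cycle index ``k >= 1``.
    """
    if cycle_index < 1:
        raise ValueError(f"cycle_index must be >= 1, got {cycle_index}")
    if annual_rate < 0:
        raise ValueError(f"annual_rate must be >= 0, got {annual_rate}")
    return (1.0 + annual_rate) ** (-(cycle_index - 1) * cycle_length_years)


@dataclass(frozen=True)
class CycleEvents:
    """Cohort fractions experiencing each event during one cycle."""

    cv_deaths: np.ndarray          # by NYHA state of origin
    noncv_deaths: np.ndarray       # by NYHA state of origin
    first_admissions: np.ndarray   # by NYHA state at admission
    readmissions: np.ndarray       # by NYHA state at admission

    @property
    def admissions(self) -> np.ndarray:
        """Total admissions (first plus readmissions) by NYHA state."""
        return self.first_admissions + self.readmissions

    @property
    def deaths(self) -> float:
        return float(self.cv_deaths.sum() + self.noncv_deaths.sum())


def step_cycle(state_vector: np.ndarray, events: EventRates,
               transition: TransitionMatrix,
               background: BackgroundMortality,
               age: float) -> tuple[np.ndarray, CycleEvents]:
    """Advance the cohort one cycle; returns (next state vector, events).

    ``state_vector`` holds fractions over the five states and must sum to 1.
    Death probabilities are combined additively (CV + non-CV at the attained
    age) and clamped at 1 with a warning; deaths are split proportionally by
    cause.  Survivors are hospitalized with ``p_hosp`` (a readmission follows
    with ``p_readmit`` in the same cycle and state), then transition between
    NYHA classes.  The DEAD mass is carried forward unchanged.
    """
    s = np.asarray(state_vector, dtype=float)
    if s.shape != (len(HealthState),):
        raise ValueError(f"state vector must have {len(HealthState)} entries")
    if abs(s.sum() - 1.0) > 1e-9:
        raise ValueError(f"state vector must sum to 1, got {s.sum()!r}")
    living = s[:N_LIVING]
    p_cv = events.p_cv_death
    p_noncv = background.rate_at(age)
    p_death = p_cv + p_noncv
    if p_death > 1.0:
        warnings.warn(
            f"p_cv + p_noncv = {p_death:.4f} > 1 at age {age:.2f}; clamped",
            RuntimeWarning, stacklevel=2)
        log.warning("combined death probability %.4f clamped to 1", p_death)
        p_death = 1.0
    deaths = living * p_death
    cv_share = p_cv / p_death if p_death > 0 else 0.0
    cv_deaths = deaths * cv_share
    noncv_deaths = deaths - cv_deaths
    survivors = living - deaths
    first_admissions = survivors * events.p_hosp
    readmissions = first_admissions * events.p_readmit
    nxt = np.empty_like(s)
    nxt[:N_LIVING] = survivors @ transition.probs
    nxt[HealthState.DEAD] = s[HealthState.DEAD] + deaths.sum()
    return nxt, CycleEvents(cv_deaths, noncv_deaths, first_admissions,
                            readmissions)


@dataclass(frozen=True)
class CycleLedger:
    """Cost and QALY contributions of one cycle, discounted and not."""

    cycle_index: int
    age: float
    drug_cost: float
    hosp_cost: float
    utility_gain: float
    disutility_loss: float   # <= 0
    life_years: float
    disc_drug_cost: float
    disc_hosp_cost: float
    disc_utility_gain: float
    disc_disutility_loss: float

    @property
    def cost(self) -> float:
        return self.drug_cost + self.hosp_cost

    @property
    def disc_cost(self) -> float:
        return self.disc_drug_cost + self.disc_hosp_cost

    @property
    def qaly(self) -> float:
        return self.utility_gain + self.disutility_loss

    @property
    def disc_qaly(self) -> float:
        return self.disc_utility_gain + self.disc_disutility_loss


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle membership and event fractions for one arm.

    ``membership`` has one row per cycle boundary (``n_cycles + 1`` rows,
    five columns); the event arrays have one row per cycle.
    """

    arm_name: str
    ages: np.ndarray               # age at each cycle start, n_cycles entries
    membership: np.ndarray         # (n_cycles + 1, 5)
    cv_deaths: np.ndarray          # (n_cycles,)
    noncv_deaths: np.ndarray       # (n_cycles,)
    first_admissions: np.ndarray   # (n_cycles, 4)
    readmissions: np.ndarray       # (n_cycles, 4)

    def to_frame(self, ledgers: list[CycleLedger] | None = None):
        """One row per cycle with membership at the cycle start plus events.

        Columns: cycle, age, NYHA1..NYHA4, DEAD, cv_deaths, noncv_deaths,
        admissions, readmissions and, when ledgers are given, disc_cost and
        disc_qaly.  A terminal row carries the final membership.
        """
        import pandas as pd

        n = len(self.ages)
        rows = {
            "cycle": np.arange(1, n + 2),
            "age": np.append(self.ages, self.ages[-1] + 0.25),
            "NYHA1": self.membership[:, 0],
            "NYHA2": self.membership[:, 1],
            "NYHA3": self.membership[:, 2],
            "NYHA4": self.membership[:, 3],
            "DEAD": self.membership[:, 4],
            "cv_deaths": np.append(self.cv_deaths, np.nan),
            "noncv_deaths": np.append(self.noncv_deaths, np.nan),
            "admissions": np.append(self.first_admissions.sum(axis=1), np.nan),
            "readmissions": np.append(self.readmissions.sum(axis=1), np.nan),
        }
        if ledgers is not None:
            rows["disc_cost"] = np.append([l.disc_cost for l in ledgers], np.nan)
            rows["disc_qaly"] = np.append([l.disc_qaly for l in ledgers], np.nan)
        return pd.DataFrame(rows)


def run_cohort(config: ModelConfig, arm_name: str) -> tuple[CohortTrace,
                                                            list[CycleLedger]]:
    """Run the full-horizon cohort recursion for one arm."""
    arm = config.arm(arm_name)
    n = config.n_cycles
    dt = config.cycle_length_years
    u = config.utilities.u_by_state
    du = config.utilities.disutility_by_state
    c_hosp = arm.costs.c_hosp_by_state

    membership = np.zeros((n + 1, len(HealthState)))
    membership[0, :N_LIVING] = config.initial_distribution
    ages = config.baseline_age + dt * np.arange(n)
    cv_deaths = np.zeros(n)
    noncv_deaths = np.zeros(n)
    first_adm = np.zeros((n, N_LIVING))
    readm = np.zeros((n, N_LIVING))
    ledgers: list[CycleLedger] = []

    s = membership[0]
    for k in range(1, n + 1):
        age = ages[k - 1]
        nxt, ev = step_cycle(s, arm.events, config.transition,
                             config.background_mortality, age)
        membership[k] = nxt
        cv_deaths[k - 1] = ev.cv_deaths.sum()
        noncv_deaths[k - 1] = ev.noncv_deaths.sum()
        first_adm[k - 1] = ev.first_admissions
        readm[k - 1] = ev.readmissions

        # trapezoidal half-cycle correction for state-occupancy quantities
        occupancy = 0.5 * (s[:N_LIVING] + nxt[:N_LIVING])
        living = occupancy.sum()
        df = discount_factor(k, config.discount_rate_annual, dt)
        admissions = ev.admissions
        drug = arm.costs.drug_cost(k) * living
        hosp = float(admissions @ c_hosp)
        gain = float(occupancy @ u)
        loss = float(admissions @ du)
        ledgers.append(CycleLedger(
            cycle_index=k, age=age,
            drug_cost=drug, hosp_cost=hosp,
            utility_gain=gain, disutility_loss=loss,
            life_years=living * dt,
            disc_drug_cost=df * drug, disc_hosp_cost=df * hosp,
            disc_utility_gain=df * gain, disc_disutility_loss=df * loss,
        ))
        s = nxt

    trace = CohortTrace(arm_name=arm_name, ages=ages, membership=membership,
                        cv_deaths=cv_deaths, noncv_deaths=noncv_deaths,
                        first_admissions=first_adm, readmissions=readm)
    return trace, ledgers
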