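"""Cohort engine: cycle mechanics, invariants and ledger accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfcua import (
    BackgroundMortality,
    EventRates,
    ScenarioSpec,
    TransitionMatrix,
    arm_outcome,
    discount_factor,
    generate_scenario,
    run_cohort,
    step_cycle,
)

from conftest import set_arm_events, zero_event_config


@pytest.mark.parametrize("k, rate, expected", [
    (1, 0.05, 1.0),                  # first cycle undiscounted
    (5, 0.05, 1.0 / 1.05),           # one elapsed year
    (9, 0.05, 1.0 / 1.05 ** 2),
    (17, 0.0, 1.0),                  # zero-rate identity
])
def test_discount_factor(k, rate, expected):
    assert discount_factor(k, rate, 0.25) == pytest.approx(expected, rel=1e-12)


def test_discount_factor_rejects_invalid():
    with pytest.raises(ValueError):
        discount_factor(0, 0.05, 0.25)
    with pytest.raises(ValueError):
        discount_factor(1, -0.01, 0.25)


BG = BackgroundMortality(((68.0, 70.0, 0.00244), (71.0, 75.0, 0.00312),
                          (76.0, 80.0, 0.00450)))


def test_step_cycle_dead_state_is_absorbing(cfg):
    s = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    nxt, ev = step_cycle(s, cfg.arm("standard").events, cfg.transition, BG, 70.0)
    assert nxt.tolist() == s.tolist()
    assert ev.deaths == 0.0
    assert ev.admissions.sum() == 0.0


def test_step_cycle_additive_competing_mortality(cfg):
    """CV and background death combine additively: 0.0233 + 0.00244."""
    s = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    nxt, ev = step_cycle(s, cfg.arm("vericiguat").events, cfg.transition, BG, 67.3)
    assert ev.deaths == pytest.approx(0.02574, abs=1e-12)
    assert ev.cv_deaths.sum() == pytest.approx(1.0 * 0.0233, rel=1e-9)
    assert ev.noncv_deaths.sum() == pytest.approx(1.0 * 0.00244, rel=1e-9)
    assert nxt.sum() == pytest.approx(1.0, abs=1e-12)


def test_step_cycle_identity_is_a_fixed_point(cfg):
    s = np.array([0.1, 0.5, 0.3, 0.1, 0.0])
    no_bg = BackgroundMortality(((0.0, 200.0, 0.0),))
    nxt, ev = step_cycle(s, EventRates(0.0, 0.0, 0.0),
                         TransitionMatrix(np.eye(4)), no_bg, 70.0)
    assert nxt == pytest.approx(s, abs=1e-15)
    assert ev.deaths == 0.0


def test_step_cycle_expected_admissions(cfg):
    """Admissions per cycle = survivors x p_hosp x (1 + p_readmit)."""
    s = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    ev_rates = cfg.arm("standard").events
    _nxt, ev = step_cycle(s, ev_rates, cfg.transition, BG, 67.3)
    survivors = 1.0 - (ev_rates.p_cv_death + 0.00244)
    assert ev.admissions.sum() == pytest.approx(
        survivors * 0.0929 * 1.7885, rel=1e-9)
    assert ev.readmissions.sum() == pytest.approx(
        ev.first_admissions.sum() * 0.7885, rel=1e-12)


def test_step_cycle_clamps_excess_mortality(cfg):
    s = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    bg = BackgroundMortality(((0.0, 200.0, 0.5),))
    with pytest.warns(RuntimeWarning, match="clamped"):
        nxt, ev = step_cycle(s, EventRates(0.7, 0.0, 0.0), cfg.transition,
                             bg, 70.0)
    assert ev.deaths == pytest.approx(1.0)
    assert nxt[4] == pytest.approx(1.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    mass=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5).filter(
        lambda v: sum(v) > 1e-6),
    p_cv=st.floats(0.0, 0.3), p_hosp=st.floats(0.0, 0.5),
    p_readmit=st.floats(0.0, 1.0),
)
def test_step_cycle_conserves_mass(cfg, mass, p_cv, p_hosp, p_readmit):
    s = np.array(mass) / sum(mass)
    nxt, ev = step_cycle(s, EventRates(p_cv, p_hosp, p_readmit),
                         cfg.transition, BG, 72.0)
    assert nxt.sum() == pytest.approx(1.0, abs=1e-9)
    assert (nxt >= -1e-15).all()
    assert nxt[4] >= s[4] - 1e-15


def test_single_cycle_closed_form(cfg):
    """One event-free cycle in NYHA I yields QALY = u1 and LY = 1/4 year."""
    one = zero_event_config(cfg, horizon_years=0.25)
    for arm in one.arm_names:
        trace, ledgers = run_cohort(one, arm)
        assert len(ledgers) == 1
        assert sum(l.disc_qaly for l in ledgers) == pytest.approx(0.2138, abs=1e-12)
        assert sum(l.life_years for l in ledgers) == pytest.approx(0.25, abs=1e-12)
        assert trace.membership[-1, 0] == pytest.approx(1.0)


def test_zero_discount_matches_undiscounted_ledger(cfg):
    flat = cfg.with_updates(discount_rate_annual=0.0)
    _trace, ledgers = run_cohort(flat, "standard")
    assert sum(l.disc_qaly for l in ledgers) == pytest.approx(
        sum(l.qaly for l in ledgers), rel=1e-12)
    assert sum(l.disc_cost for l in ledgers) == pytest.approx(
        sum(l.cost for l in ledgers), rel=1e-12)


def test_ledger_discounting_never_exceeds_undiscounted(cfg):
    _trace, ledgers = run_cohort(cfg, "vericiguat")
    for l in ledgers:
        assert l.disc_cost <= l.cost + 1e-12
        assert l.disc_utility_gain <= l.utility_gain + 1e-12
        assert l.drug_cost >= 0 and l.hosp_cost >= 0
        assert l.disutility_loss <= 0


@pytest.mark.parametrize("seed", range(20))
def test_mass_conservation_and_monotone_death_on_random_scenarios(seed):
    scenario = generate_scenario(ScenarioSpec.randomized(seed))
    for arm in scenario.arm_names:
        trace, _ledgers = run_cohort(scenario, arm)
        sums = trace.membership.sum(axis=1)
        assert sums == pytest.approx(np.ones_like(sums), abs=1e-9)
        dead = trace.membership[:, 4]
        assert (np.diff(dead) >= -1e-15).all()
        # any positive death probability keeps killing while anyone lives
        living = 1.0 - dead
        strictly = np.diff(dead)[living[:-1] > 1e-12]
        assert (strictly > 0).all()


def test_raising_costs_cannot_reduce_total_cost(cfg):
    from dataclasses import replace

    base = arm_outcome(cfg, "standard").total_cost
    arm = cfg.arm("standard")
    arms = dict(cfg.arms)
    arms["standard"] = replace(arm, costs=replace(
        arm.costs, c_hosp_by_state=arm.costs.c_hosp_by_state * 1.5))
    assert arm_outcome(cfg.with_updates(arms=arms), "standard").total_cost > base


def test_raising_cv_mortality_cannot_increase_qalys(cfg):
    base = arm_outcome(cfg, "standard").total_qalys
    worse = set_arm_events(cfg, "standard", p_cv_death=0.05)
    assert arm_outcome(worse, "standard").total_qalys < base


def test_discounting_monotonically_reduces_qalys(cfg):
    totals = [arm_outcome(cfg.with_updates(discount_rate_annual=r),
                          "vericiguat").total_qalys
              for r in (0.0, 0.03, 0.05, 0.08)]
    assert totals == sorted(totals, reverse=True)


def test_trace_export_columns(cfg):
    trace, ledgers = run_cohort(cfg, "standard")
    frame = trace.to_frame(ledgers)
    assert list(frame.columns) == [
        "cycle", "age", "NYHA1", "NYHA2", "NYHA3", "NYHA4", "DEAD",
        "cv_deaths", "noncv_deaths", "admissions", "readmissions",
        "disc_cost", "disc_qaly"]
    assert len(frame) == cfg.n_cycles + 1
    assert frame["age"].iloc[0] == 67.3
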