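"""One-way sensitivity analysis, tornado ordering and the PSA machinery."""

import numpy as np
import pytest

from hfcua import ParamDistribution, ValidationError, one_way_sa, run_psa, sample_psa_params
from hfcua.sensitivity import (
    apply_param,
    base_value,
    default_oneway_ranges,
    sa_parameter_names,
    tornado_frame,
)


def test_base_values_resolve_for_all_ranged_parameters(cfg):
    for name in default_oneway_ranges(cfg):
        low, high = default_oneway_ranges(cfg)[name]
        assert low <= base_value(cfg, name) <= high, name


def test_apply_param_round_trip_leaves_base_unchanged(cfg):
    tweaked = apply_param(cfg, "utility.nyha2", 0.19)
    assert tweaked.utilities.u_by_state[1] == 0.19
    assert cfg.utilities.u_by_state[1] == 0.1865  # original untouched
    tweaked = apply_param(cfg, "cost.vericiguat_cycle", 2 * 5866.93)
    costs = tweaked.arm("vericiguat").costs
    # the titrated first cycle scales with the maintenance multiplier
    assert costs.c_arm_first_cycle == pytest.approx(2 * 4887.77)
    assert costs.c_arm_later_cycle == pytest.approx(2 * 5866.93)


def test_unknown_parameter_is_reported_with_valid_names(cfg):
    with pytest.raises(ValidationError, match="standard.p_cv_death"):
        one_way_sa(cfg, {"not.a.param": (0.0, 1.0)})


def test_degenerate_range_reproduces_base_icur(cfg, base_result):
    *_outs, res = base_result
    entries = one_way_sa(cfg, {"utility.nyha2": (0.1865, 0.1865)})
    assert entries[0].icur_at_low == pytest.approx(res.icur, rel=1e-12)
    assert entries[0].icur_at_high == pytest.approx(res.icur, rel=1e-12)


def test_one_way_tornado_structure(cfg, base_result):
    entries = one_way_sa(cfg)
    # the published table varies 15 parameters
    assert len(entries) == 15
    spreads = [e.spread for e in entries]
    assert spreads == sorted(spreads, reverse=True)
    # CV mortality in the two arms dominates the tornado
    top_two = {entries[0].parameter_name, entries[1].parameter_name}
    assert top_two == {"standard.p_cv_death", "vericiguat.p_cv_death"}
    by_name = {e.parameter_name: e for e in entries}
    disc = by_name["discount_rate"]
    assert disc.low_value == 0.0 and disc.high_value == 0.08
    # a lower discount rate favours the survival-extending arm
    assert disc.icur_at_low < disc.icur_at_high
    *_outs, res = base_result
    assert disc.icur_at_low < res.icur < disc.icur_at_high
    frame = tornado_frame(entries)
    assert list(frame["parameter"]) == [e.parameter_name for e in entries]


def test_sampled_config_determinism(cfg):
    a = sample_psa_params(cfg, 123)
    b = sample_psa_params(cfg, 123)
    assert a.transition.probs.tolist() == b.transition.probs.tolist()
    assert a.arm("standard").events.p_cv_death == b.arm("standard").events.p_cv_death
    assert a.utilities.u_by_state.tolist() == b.utilities.u_by_state.tolist()
    c = sample_psa_params(cfg, 124)
    assert a.arm("standard").events.p_cv_death != c.arm("standard").events.p_cv_death


def test_sampled_transition_rows_are_stochastic_with_structural_zeros(cfg):
    for seed in range(10):
        sampled = sample_psa_params(cfg, seed)
        probs = sampled.transition.probs
        assert probs.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-12)
        # zero-probability cells of the base matrix stay exactly zero
        assert (probs[cfg.transition.probs == 0.0] == 0.0).all()


def test_fixed_and_unranged_parameters_are_never_sampled(cfg):
    sampled = sample_psa_params(cfg, 7)
    assert sampled.discount_rate_annual == cfg.discount_rate_annual
    for arm in cfg.arm_names:
        assert sampled.arm(arm).events.p_readmit == cfg.arm(arm).events.p_readmit
    assert sampled.utilities.disutility_by_state.tolist() == \
        cfg.utilities.disutility_by_state.tolist()


def test_beta_event_sampling_matches_published_mean(cfg):
    dist = cfg.distributions["vericiguat.p_cv_death"]
    rng = np.random.default_rng(99)
    draws = np.array([dist.sample(rng) for _ in range(100_000)])
    se = np.sqrt(0.0233 * 0.9767 / 101.0) / np.sqrt(draws.size)
    assert abs(draws.mean() - 0.0233) < 3 * se


def test_vericiguat_cost_draw_preserves_titration_ratio(cfg):
    sampled = sample_psa_params(cfg, 5)
    costs = sampled.arm("vericiguat").costs
    assert costs.c_arm_first_cycle / costs.c_arm_later_cycle == pytest.approx(
        4887.77 / 5866.93, rel=1e-12)


def test_psa_point_masses_reproduce_base_case(cfg, base_result):
    *_outs, res = base_result
    frozen = {
        name: ParamDistribution("fixed", {"value": base_value(cfg, name)})
        for name in default_oneway_ranges(cfg)
    }
    degenerate = cfg.with_updates(distributions=frozen)
    psa = run_psa(degenerate, 5, seed=1)
    assert psa.draws[:, 0] == pytest.approx(np.full(5, res.delta_cost), rel=1e-12)
    assert psa.draws[:, 1] == pytest.approx(np.full(5, res.delta_effect), rel=1e-12)


def test_psa_seed_reproducibility(cfg):
    a = run_psa(cfg, 50, seed=11)
    b = run_psa(cfg, 50, seed=11)
    assert (a.draws == b.draws).all()
    c = run_psa(cfg, 50, seed=12)
    assert (a.draws != c.draws).any()


def test_acceptance_probability_definitions(cfg):
    psa = run_psa(cfg, 200, seed=3)
    assert psa.acceptance_probability(0.0) == pytest.approx(
        float(np.mean(psa.draws[:, 0] < 0)))
    ceac = psa.ceac()
    assert ceac.shape == (101, 2)
    assert ((ceac[:, 1] >= 0) & (ceac[:, 1] <= 1)).all()
    assert ceac[0, 0] == 0.0 and ceac[-1, 0] == 500_000.0
    # the CEAC passes through the pointwise acceptance probability
    wtp = 257100.0
    frame = psa.ceac_frame([wtp])
    assert frame.loc[0, "probability"] == psa.acceptance_probability(wtp)


def test_invalid_iteration_count_rejected(cfg):
    with pytest.raises(ValidationError):
        run_psa(cfg, 0, seed=1)
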