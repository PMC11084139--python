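"""Deterministic one-way sensitivity analysis and probabilistic sensitivity
analysis (PSA) with cost-effectiveness acceptability curve.

Parameters are addressed by dotted names matching the keys of
``ModelConfig.distributions``:

``<arm>.p_cv_death`` / ``<arm>.p_hosp``
    per-arm event probabilities;
``cost.standard_cycle``
    per-cycle basic-regimen cost, applied to the comparator (first) arm —
    the published one-way analysis varies the standard arm alone;
``cost.vericiguat_cycle``
    combined per-cycle medication cost of the intervention (second) arm;
    varied or sampled as a multiplier of the maintenance-cycle cost so the
    titrated first cycle keeps its ratio to later cycles;
``cost.hosp_nyha1`` .. ``cost.hosp_nyha4``
    per-admission costs, shared by both arms;
``utility.nyha1`` .. ``utility.nyha4``
    3-month state utilities;
``discount_rate``
    annual discount rate;
``transition.nyha1`` .. ``transition.nyha4``
    transition-matrix rows (PSA only; Dirichlet).

Parameters published without an uncertainty range (readmission
probabilities, background mortality, disutilities) are held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .config import ModelConfig, TransitionMatrix, ValidationError
from .outcomes import run_cua

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "sa_parameter_names",
    "base_value",
    "apply_param",
    "one_way_sa",
    "sample_psa_params",
    "run_psa",
    "tornado_frame",
]

_HOSP = {f"cost.hosp_nyha{i + 1}": i for i in range(4)}
_UTIL = {f"utility.nyha{i + 1}": i for i in range(4)}
_TRANS = {f"transition.nyha{i + 1}": i for i in range(4)}


def sa_parameter_names(config: ModelConfig) -> list[str]:
    """All addressable scalar parameter names for this config."""
    names = []
    for arm in config.arm_names:
        names += [f"{arm}.p_cv_death", f"{arm}.p_hosp"]
    names += ["cost.standard_cycle", "cost.vericiguat_cycle"]
    names += list(_HOSP) + list(_UTIL) + ["discount_rate"]
    return names


def _unknown(config: ModelConfig, name: str) -> ValidationError:
    return ValidationError(
        f"unknown parameter {name!r}; valid names: "
        + ", ".join(sa_parameter_names(config)))


def base_value(config: ModelConfig, name: str) -> float:
    """Deterministic base-case value of a named scalar parameter."""
    head, _, tail = name.partition(".")
    if head in config.arms and tail in ("p_cv_death", "p_hosp"):
        return getattr(config.arm(head).events, tail)
    if name == "cost.standard_cycle":
        return config.arm(config.arm_names[0]).costs.c_standard_cycle
    if name == "cost.vericiguat_cycle":
        return config.arm(config.arm_names[1]).costs.c_arm_later_cycle
    if name in _HOSP:
        return float(config.arm(config.arm_names[0])
                     .costs.c_hosp_by_state[_HOSP[name]])
    if name in _UTIL:
        return float(config.utilities.u_by_state[_UTIL[name]])
    if name == "discount_rate":
        return config.discount_rate_annual
    raise KeyError(name)


def apply_param(config: ModelConfig, name: str, value: float) -> ModelConfig:
    """Return a copy of the config with one named parameter replaced."""
    head, _, tail = name.partition(".")
    arms = dict(config.arms)
    if head in arms and tail in ("p_cv_death", "p_hosp"):
        arm = arms[head]
        arms[head] = replace(arm, events=replace(arm.events, **{tail: value}))
        return config.with_updates(arms=arms)
    if name == "cost.standard_cycle":
        comp = arms[config.arm_names[0]]
        arms[comp.name] = replace(comp, costs=replace(
            comp.costs, c_standard_cycle=value,
            c_arm_first_cycle=value, c_arm_later_cycle=value))
        return config.with_updates(arms=arms)
    if name == "cost.vericiguat_cycle":
        interv = arms[config.arm_names[1]]
        mult = value / interv.costs.c_arm_later_cycle
        arms[interv.name] = replace(interv, costs=replace(
            interv.costs,
            c_arm_first_cycle=interv.costs.c_arm_first_cycle * mult,
            c_arm_later_cycle=value))
        return config.with_updates(arms=arms)
    if name in _HOSP:
        for arm_name, arm in arms.items():
            hosp = arm.costs.c_hosp_by_state.copy()
            hosp[_HOSP[name]] = value
            arms[arm_name] = replace(arm, costs=replace(
                arm.costs, c_hosp_by_state=hosp))
        return config.with_updates(arms=arms)
    if name in _UTIL:
        u = config.utilities.u_by_state.copy()
        u[_UTIL[name]] = value
        return config.with_updates(utilities=replace(
            config.utilities, u_by_state=u))
    if name == "discount_rate":
        return config.with_updates(discount_rate_annual=value)
    raise _unknown(config, name)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    """ICUR excursion of one parameter over its one-way range."""

    parameter_name: str
    low_value: float
    high_value: float
    icur_at_low: float
    icur_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icur_at_high - self.icur_at_low)


def default_oneway_ranges(config: ModelConfig) -> dict[str, tuple[float, float]]:
    """(low, high) per parameter, from the distributions carrying bounds."""
    out = {}
    for name, dist in config.distributions.items():
        if dist.low is not None and dist.high is not None:
            out[name] = (dist.low, dist.high)
    return out


def one_way_sa(config: ModelConfig,
               parameter_ranges: Mapping[str, tuple[float, float]] | None = None,
               ) -> list[TornadoEntry]:
    """Re-run the model with each parameter at its bounds, others at base.

    Returns entries sorted by descending ICUR spread (tornado order).  The
    input config is never modified.
    """
    if parameter_ranges is None:
        parameter_ranges = default_oneway_ranges(config)
    entries = []
    for name, (low, high) in parameter_ranges.items():
        try:
            base = base_value(config, name)
        except KeyError:
            raise _unknown(config, name) from None
        if not low <= base <= high:
            raise ValidationError(
                f"{name}: one-way range ({low}, {high}) does not bracket the "
                f"base value {base}")
        icurs = []
        for v in (low, high):
            *_outs, res = run_cua(apply_param(config, name, v))
            if res.icur is None:
                raise ValidationError(f"{name}={v}: ICUR undefined")
            icurs.append(res.icur)
        entries.append(TornadoEntry(name, low, high, icurs[0], icurs[1]))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry]):
    """Tornado table as a DataFrame (one row per parameter)."""
    import pandas as pd

    return pd.DataFrame([{
        "parameter": e.parameter_name,
        "low_value": e.low_value,
        "high_value": e.high_value,
        "icur_at_low": e.icur_at_low,
        "icur_at_high": e.icur_at_high,
        "spread": e.spread,
    } for e in entries])


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def sample_psa_params(config: ModelConfig,
                      rng: np.random.Generator | int) -> ModelConfig:
    """Draw one probabilistic parameter set from the config's distributions.

    Beta draws replace event probabilities and utilities, Gamma draws replace
    costs (the intervention-arm medication cost through a single multiplier
    preserving the titration ratio), Dirichlet draws replace transition rows.
    ``fixed`` entries and parameters without a distribution stay at base.
    Draws are taken in sorted parameter-name order, so a given generator
    state always yields the same sampled config.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = config
    new_rows = {}
    for name in sorted(config.distributions):
        dist = config.distributions[name]
        if dist.kind == "fixed":
            continue
        draw = dist.sample(rng)
        if name in _TRANS:
            new_rows[_TRANS[name]] = draw
        else:
            if name in _UTIL:
                # Beta draws live on [0, 1]; a 3-month utility cannot exceed
                # 0.25 (perfect health), so the rare upper tail is clipped
                draw = min(float(draw), 0.25)
            out = apply_param(out, name, float(draw))
    if new_rows:
        probs = out.transition.probs.copy()
        for i, row in new_rows.items():
            probs[i] = row
        out = out.with_updates(transition=TransitionMatrix(probs))
    return out


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo draws of (incremental cost, incremental effect)."""

    draws: np.ndarray        # (n_iterations, 2): delta_cost, delta_effect
    n_iterations: int
    seed: int
    intervention: str
    comparator: str

    def acceptance_probability(self, wtp: float) -> float:
        """Fraction of draws with positive incremental net monetary benefit."""
        dc, de = self.draws[:, 0], self.draws[:, 1]
        return float(np.mean(wtp * de - dc > 0))

    def ceac(self, wtp_grid: Sequence[float] | None = None) -> np.ndarray:
        """Cost-effectiveness acceptability curve over a WTP grid.

        Default grid: 0 to 500,000 CNY in steps of 5,000.  Returns an array
        of (wtp, probability) rows.
        """
        if wtp_grid is None:
            wtp_grid = np.arange(0.0, 500_000.0 + 1, 5_000.0)
        grid = np.asarray(list(wtp_grid), dtype=float)
        probs = [self.acceptance_probability(w) for w in grid]
        return np.column_stack([grid, probs])

    def ce_plane_frame(self):
        """Scatter data for the cost-effectiveness plane, one row per draw."""
        import pandas as pd

        return pd.DataFrame({
            "iteration": np.arange(1, self.n_iterations + 1),
            "delta_cost": self.draws[:, 0],
            "delta_effect": self.draws[:, 1],
        })

    def ceac_frame(self, wtp_grid: Sequence[float] | None = None):
        import pandas as pd

        arr = self.ceac(wtp_grid)
        return pd.DataFrame({"wtp": arr[:, 0], "probability": arr[:, 1]})


def run_psa(config: ModelConfig, n_iterations: int, seed: int) -> PSAResult:
    """Monte-Carlo PSA: sample parameters, run both arms, record increments.

    Each iteration uses an independent substream spawned deterministically
    from the master seed, so (config, n_iterations, seed) fully determines
    the result.
    """
    if n_iterations < 1:
        raise ValidationError(f"n_iterations must be >= 1, got {n_iterations}")
    comparator, intervention = config.arm_names
    ss = np.random.SeedSequence(seed)
    draws = np.empty((n_iterations, 2))
    for i, child in enumerate(ss.spawn(n_iterations)):
        rng = np.random.default_rng(child)
        try:
            sampled = sample_psa_params(config, rng)
            out_i, out_c, res = run_cua(sampled, intervention, comparator)
        except Exception as exc:
            raise RuntimeError(
                f"PSA iteration {i + 1} (master seed {seed}) failed: {exc}"
            ) from exc
        draws[i] = (res.delta_cost, res.delta_effect)
    return PSAResult(draws=draws, n_iterations=n_iterations, seed=seed,
                     intervention=intervention, comparator=comparator)
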