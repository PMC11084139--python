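"""Model configuration: domain types, validation, distributions and file I/O.

A :class:`ModelConfig` is a complete, immutable description of one two-arm
cost-utility scenario: a five-state Markov structure (NYHA I-IV plus death),
arm-specific event probabilities and drug costs, shared transition matrix,
background mortality, utilities, discounting and the willingness-to-pay
threshold.  The bundled ``vericiguat_base_case`` fixture encodes the published
Chinese vericiguat-vs-standard-treatment scenario in 2022 CNY.

Probabilities are stored as fractions (0.0233, not 2.33%); percentages appear
only at the I/O boundary of :func:`beta_from_percent`.  Monetary amounts are
kept at full floating precision internally; rounding to 2 decimals happens in
reports only.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "HealthState",
    "ConfigError",
    "ValidationError",
    "TransitionMatrix",
    "EventRates",
    "BackgroundMortality",
    "CostInputs",
    "UtilityInputs",
    "VericiguatPricing",
    "ParamDistribution",
    "Arm",
    "ModelConfig",
    "inflate_cost",
    "gamma_from_mean_sd",
    "beta_from_percent",
    "load_config",
    "write_config",
    "base_case",
    "parameter_table",
]

SCHEMA_VERSION = 1
_ATOL = 1e-9


class HealthState(enum.IntEnum):
    """The five Markov states.  DEAD is absorbing."""

    NYHA1 = 0
    NYHA2 = 1
    NYHA3 = 2
    NYHA4 = 3
    DEAD = 4


N_LIVING = 4
N_STATES = 5
LIVING_STATES = tuple(HealthState(i) for i in range(N_LIVING))


class ConfigError(ValueError):
    """Raised when a config file cannot be parsed into the documented schema."""


class ValidationError(ValueError):
    """Raised when a parsed configuration violates a model invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# Scalar helpers
# ---------------------------------------------------------------------------

def inflate_cost(base: float, factors: Sequence[float]) -> float:
    """Carry a cost forward through a chain of annual inflation multipliers.

    Returns ``base * prod(factors)`` rounded to 2 decimals (the reporting
    precision for CNY amounts).  An empty chain is the identity.
    """
    if base < 0:
        raise ValidationError(f"cost to inflate must be >= 0, got {base}")
    for f in factors:
        if f <= 0:
            raise ValidationError(f"inflation factor must be > 0, got {f}")
    return round(base * math.prod(factors), 2)


@dataclass(frozen=True)
class ParamDistribution:
    """Uncertainty description of one model parameter.

    ``kind`` is one of ``beta`` (hyperparams ``alpha``, ``beta``), ``gamma``
    (``shape``, ``scale``), ``dirichlet`` (``concentration`` vector) or
    ``fixed`` (``value``).  ``low``/``high`` are the deterministic one-way
    sensitivity bounds, when the analysis defines them.
    """

    kind: str
    hyperparams: Mapping[str, object]
    low: float | None = None
    high: float | None = None

    _KINDS = ("beta", "gamma", "dirichlet", "fixed")

    def __post_init__(self) -> None:
        _require(self.kind in self._KINDS, f"unknown distribution kind {self.kind!r}")
        for name, v in self.hyperparams.items():
            if name == "concentration":
                arr = np.asarray(v, dtype=float)
                _require((arr >= 0).all(), "dirichlet concentrations must be >= 0")
                _require(arr.sum() > 0, "dirichlet needs a positive concentration")
            elif name != "value":
                _require(float(v) > 0, f"hyperparameter {name} must be > 0, got {v}")
        if self.low is not None and self.high is not None:
            _require(self.low <= self.high, "one-way bounds require low <= high")

    @property
    def mean(self) -> float:
        """Analytic mean (scalar kinds only)."""
        h = self.hyperparams
        if self.kind == "beta":
            a, b = float(h["alpha"]), float(h["beta"])
            return a / (a + b)
        if self.kind == "gamma":
            return float(h["shape"]) * float(h["scale"])
        if self.kind == "fixed":
            return float(h["value"])
        raise ValueError("mean is not a scalar for dirichlet distributions")

    def sample(self, rng: np.random.Generator):
        """Draw one value (scalar, or a vector for dirichlet).

        Dirichlet components with zero concentration are structural zeros:
        they stay exactly 0 and the remaining components are renormalised
        draws, so sampled transition rows keep the sparsity of the base row.
        """
        h = self.hyperparams
        if self.kind == "beta":
            return float(rng.beta(float(h["alpha"]), float(h["beta"])))
        if self.kind == "gamma":
            return float(rng.gamma(float(h["shape"]), float(h["scale"])))
        if self.kind == "fixed":
            return float(h["value"])
        conc = np.asarray(h["concentration"], dtype=float)
        out = np.zeros_like(conc)
        pos = conc > 0
        out[pos] = rng.dirichlet(conc[pos])
        return out


def gamma_from_mean_sd(mean: float, sd: float, *, low: float | None = None,
                       high: float | None = None) -> ParamDistribution:
    """Gamma distribution by method of moments: shape=(mean/sd)^2, scale=sd^2/mean."""
    if mean <= 0 or sd <= 0:
        raise ValidationError(f"gamma needs mean > 0 and sd > 0, got {mean}, {sd}")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    # mean/sd are retained so files round-trip bit-identically
    return ParamDistribution("gamma", {"shape": shape, "scale": scale,
                                       "mean": mean, "sd": sd},
                             low=low, high=high)


def beta_from_percent(pct: float, *, low: float | None = None,
                      high: float | None = None) -> ParamDistribution:
    """Beta distribution with pseudo-count 100: alpha=pct, beta=100-pct.

    This is the parameterisation used throughout the published input tables
    (a probability of 2.33% becomes Beta(2.33, 97.67), whose mean is 0.0233).
    """
    if not 0 < pct < 100:
        raise ValidationError(f"percentage must be in (0, 100), got {pct}")
    return ParamDistribution("beta", {"alpha": pct, "beta": 100.0 - pct},
                             low=low, high=high)


# ---------------------------------------------------------------------------
# Structured inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionMatrix:
    """4x4 three-month transition probabilities among NYHA I-IV.

    Rows condition on surviving the cycle; death and hospitalization are
    layered on top by the engine.  Every row must sum to 1.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        _require(p.shape == (N_LIVING, N_LIVING),
                 f"transition matrix must be 4x4, got {p.shape}")
        _require(bool(((p >= 0) & (p <= 1)).all()),
                 "transition probabilities must lie in [0, 1]")
        bad = np.where(np.abs(p.sum(axis=1) - 1.0) > _ATOL)[0]
        _require(bad.size == 0,
                 f"transition rows must sum to 1; row(s) {bad.tolist()} do not")


@dataclass(frozen=True)
class EventRates:
    """Per-cycle (3-month) event probabilities for one treatment arm."""

    p_cv_death: float
    p_hosp: float
    p_readmit: float  # conditional on hospitalization within the same cycle

    def __post_init__(self) -> None:
        for name in ("p_cv_death", "p_hosp", "p_readmit"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class BackgroundMortality:
    """Age-bracketed 3-month non-cardiovascular death probabilities.

    Brackets must be sorted and non-overlapping.  Ages below the first
    bracket use the first rate and ages above the last use the last rate,
    so a horizon may extend slightly past the tabulated range.
    """

    brackets: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        br = tuple((float(a), float(b), float(p)) for a, b, p in self.brackets)
        object.__setattr__(self, "brackets", br)
        _require(len(br) > 0, "background mortality needs at least one bracket")
        prev_high = -math.inf
        for lo, hi, p in br:
            _require(lo <= hi, f"bracket ({lo}, {hi}) has age_low > age_high")
            _require(lo > prev_high, "brackets must be sorted and non-overlapping")
            _require(0.0 <= p <= 1.0, f"p_noncv must be in [0, 1], got {p}")
            prev_high = hi

    def rate_at(self, age: float) -> float:
        """3-month non-CV death probability at an attained age (years)."""
        rate = self.brackets[0][2]
        for lo, _hi, p in self.brackets:
            if age >= lo:
                rate = p
            else:
                break
        return rate


@dataclass(frozen=True)
class CostInputs:
    """Per-arm cost structure, in CNY (3-month cycle).

    ``c_arm_first_cycle``/``c_arm_later_cycle`` are the total per-cycle
    medication costs (for the intervention arm they include both the titrated
    add-on drug and the basic regimen whose own cost is ``c_standard_cycle``).
    """

    c_standard_cycle: float
    c_arm_first_cycle: float
    c_arm_later_cycle: float
    c_hosp_by_state: np.ndarray  # per admission, NYHA I..IV
    inflation_factors: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        hosp = np.asarray(self.c_hosp_by_state, dtype=float)
        object.__setattr__(self, "c_hosp_by_state", hosp)
        object.__setattr__(self, "inflation_factors",
                           tuple(float(f) for f in self.inflation_factors))
        _require(hosp.shape == (N_LIVING,),
                 "c_hosp_by_state needs one admission cost per NYHA class")
        for name in ("c_standard_cycle", "c_arm_first_cycle", "c_arm_later_cycle"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(bool((hosp >= 0).all()), "hospitalization costs must be >= 0")

    def drug_cost(self, cycle_index: int) -> float:
        return self.c_arm_first_cycle if cycle_index == 1 else self.c_arm_later_cycle


@dataclass(frozen=True)
class UtilityInputs:
    """3-month utility increments per NYHA class and per-admission disutilities."""

    u_by_state: np.ndarray
    disutility_by_state: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u_by_state, dtype=float)
        d = np.asarray(self.disutility_by_state, dtype=float)
        object.__setattr__(self, "u_by_state", u)
        object.__setattr__(self, "disutility_by_state", d)
        _require(u.shape == (N_LIVING,) and d.shape == (N_LIVING,),
                 "utilities and disutilities need one entry per NYHA class")
        _require(bool(((u >= 0) & (u <= 0.25)).all()),
                 "3-month utilities must lie in [0, 0.25]")
        _require(bool((d <= 0).all()), "disutilities must be <= 0")


@dataclass(frozen=True)
class VericiguatPricing:
    """Box prices and titration schedule behind the add-on drug cycle costs.

    The first 3-month cycle titrates 2.5 mg -> 5 mg -> 10 mg daily: one
    2.5 mg box, then nine 5 mg boxes (one box covers two weeks at 5 mg or one
    week at 10 mg).  Maintenance cycles use twelve 5 mg boxes.  These counts
    reconstruct the published 3892.84 / 4872 CNY cycle costs and drive the
    value-based price-threshold search.
    """

    box_5mg_cny: float
    box_2_5mg_cny: float
    boxes_first_cycle_2_5mg: float = 1.0
    boxes_first_cycle_5mg: float = 9.0
    boxes_later_cycle_5mg: float = 12.0

    def __post_init__(self) -> None:
        _require(self.box_5mg_cny >= 0 and self.box_2_5mg_cny >= 0,
                 "box prices must be >= 0")

    def cycle_costs(self, p_5mg: float | None = None) -> tuple[float, float]:
        """(first-cycle, later-cycle) add-on drug cost at a 5 mg box price.

        The 2.5 mg box is repriced proportionally with the 5 mg box.
        """
        if p_5mg is None:
            p_5mg = self.box_5mg_cny
        p_25 = self.box_2_5mg_cny * p_5mg / self.box_5mg_cny
        first = self.boxes_first_cycle_2_5mg * p_25 + self.boxes_first_cycle_5mg * p_5mg
        later = self.boxes_later_cycle_5mg * p_5mg
        return first, later


@dataclass(frozen=True)
class Arm:
    """One treatment strategy: event probabilities plus cost structure."""

    name: str
    events: EventRates
    costs: CostInputs


@dataclass(frozen=True, eq=False)
class ModelConfig:
    """Immutable description of one two-arm cost-utility scenario."""

    name: str
    horizon_years: float
    cycle_length_years: float
    baseline_age: float
    initial_distribution: np.ndarray  # over NYHA I..IV
    discount_rate_annual: float
    wtp_per_qaly: float
    transition: TransitionMatrix
    background_mortality: BackgroundMortality
    utilities: UtilityInputs
    arms: Mapping[str, Arm]
    distributions: Mapping[str, ParamDistribution] = field(default_factory=dict)
    pricing: VericiguatPricing | None = None
    notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        init = np.asarray(self.initial_distribution, dtype=float)
        object.__setattr__(self, "initial_distribution", init)
        object.__setattr__(self, "arms", dict(self.arms))
        object.__setattr__(self, "distributions", dict(self.distributions))
        object.__setattr__(self, "notes", dict(self.notes))
        _require(init.shape == (N_LIVING,),
                 "initial_distribution needs one fraction per NYHA class")
        _require(bool((init >= 0).all()), "initial_distribution must be >= 0")
        _require(abs(init.sum() - 1.0) <= _ATOL,
                 f"initial_distribution must sum to 1, got {init.sum()!r}")
        _require(self.horizon_years > 0, "horizon_years must be > 0")
        _require(self.cycle_length_years > 0, "cycle_length_years must be > 0")
        n = self.horizon_years / self.cycle_length_years
        _require(abs(n - round(n)) <= 1e-9,
                 "horizon_years must be an integer number of cycles")
        _require(0.0 <= self.discount_rate_annual <= 0.08,
                 "discount_rate_annual must lie in [0, 0.08] for this scenario")
        _require(self.wtp_per_qaly >= 0, "wtp_per_qaly must be >= 0")
        _require(len(self.arms) == 2, "exactly two arms are required")

    @property
    def n_cycles(self) -> int:
        return round(self.horizon_years / self.cycle_length_years)

    def arm(self, name: str) -> Arm:
        try:
            return self.arms[name]
        except KeyError:
            raise ValidationError(
                f"unknown arm {name!r}; known arms: {sorted(self.arms)}") from None

    @property
    def arm_names(self) -> tuple[str, str]:
        return tuple(self.arms)

    def with_updates(self, **kw) -> "ModelConfig":
        """Return a copy with top-level fields replaced (validation re-runs)."""
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------

def _dist_to_dict(d: ParamDistribution) -> dict:
    out: dict[str, object] = {"kind": d.kind}
    h = d.hyperparams
    if d.kind == "gamma":
        # persist in the mean/sd parameterisation used by the source tables
        shape, scale = float(h["shape"]), float(h["scale"])
        out["mean"] = float(h.get("mean", shape * scale))
        out["sd"] = float(h.get("sd", math.sqrt(shape) * scale))
    elif d.kind == "dirichlet":
        out["concentration"] = [float(x) for x in np.asarray(h["concentration"])]
    else:
        out.update({k: float(v) for k, v in h.items()})
    if d.low is not None:
        out["low"] = d.low
    if d.high is not None:
        out["high"] = d.high
    return out


def _dist_from_dict(name: str, d: Mapping) -> ParamDistribution:
    try:
        kind = d["kind"]
        low, high = d.get("low"), d.get("high")
        if kind == "gamma":
            return gamma_from_mean_sd(float(d["mean"]), float(d["sd"]),
                                      low=low, high=high)
        if kind == "beta":
            return ParamDistribution(
                "beta", {"alpha": float(d["alpha"]), "beta": float(d["beta"])},
                low=low, high=high)
        if kind == "dirichlet":
            return ParamDistribution(
                "dirichlet", {"concentration": [float(x) for x in d["concentration"]]},
                low=low, high=high)
        if kind == "fixed":
            return ParamDistribution("fixed", {"value": float(d["value"])},
                                     low=low, high=high)
        raise ConfigError(f"distribution {name!r}: unknown kind {kind!r}")
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"distribution {name!r} is malformed: {exc}") from exc


def config_to_dict(config: ModelConfig) -> dict:
    """Plain-python representation matching the documented file schema."""
    return {
        "schema_version": SCHEMA_VERSION,
        "name": config.name,
        "horizon_years": config.horizon_years,
        "cycle_length_years": config.cycle_length_years,
        "baseline_age": config.baseline_age,
        "discount_rate_annual": config.discount_rate_annual,
        "wtp_per_qaly": config.wtp_per_qaly,
        "initial_distribution": config.initial_distribution.tolist(),
        "transition_matrix": config.transition.probs.tolist(),
        "background_mortality": [
            {"age_low": lo, "age_high": hi, "p_noncv": p}
            for lo, hi, p in config.background_mortality.brackets
        ],
        "utilities": {
            "u_by_state": config.utilities.u_by_state.tolist(),
            "disutility_by_state": config.utilities.disutility_by_state.tolist(),
        },
        "arms": {
            arm.name: {
                "events": {
                    "p_cv_death": arm.events.p_cv_death,
                    "p_hosp": arm.events.p_hosp,
                    "p_readmit": arm.events.p_readmit,
                },
                "costs": {
                    "c_standard_cycle": arm.costs.c_standard_cycle,
                    "c_arm_first_cycle": arm.costs.c_arm_first_cycle,
                    "c_arm_later_cycle": arm.costs.c_arm_later_cycle,
                    "c_hosp_by_state": arm.costs.c_hosp_by_state.tolist(),
                    "inflation_factors": list(arm.costs.inflation_factors),
                },
            }
            for arm in config.arms.values()
        },
        **({"pricing": {
            "box_5mg_cny": config.pricing.box_5mg_cny,
            "box_2_5mg_cny": config.pricing.box_2_5mg_cny,
            "boxes_first_cycle_2_5mg": config.pricing.boxes_first_cycle_2_5mg,
            "boxes_first_cycle_5mg": config.pricing.boxes_first_cycle_5mg,
            "boxes_later_cycle_5mg": config.pricing.boxes_later_cycle_5mg,
        }} if config.pricing is not None else {}),
        "distributions": {k: _dist_to_dict(v)
                          for k, v in config.distributions.items()},
        **({"notes": dict(config.notes)} if config.notes else {}),
    }


def config_from_dict(raw: Mapping) -> ModelConfig:
    try:
        version = raw.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version}")
        arms = {}
        for arm_name, a in raw["arms"].items():
            ev = a["events"]
            co = a["costs"]
            arms[arm_name] = Arm(
                name=arm_name,
                events=EventRates(float(ev["p_cv_death"]), float(ev["p_hosp"]),
                                  float(ev["p_readmit"])),
                costs=CostInputs(
                    c_standard_cycle=float(co["c_standard_cycle"]),
                    c_arm_first_cycle=float(co["c_arm_first_cycle"]),
                    c_arm_later_cycle=float(co["c_arm_later_cycle"]),
                    c_hosp_by_state=co["c_hosp_by_state"],
                    inflation_factors=tuple(co.get("inflation_factors", ())),
                ),
            )
        pricing = None
        if "pricing" in raw:
            pricing = VericiguatPricing(**{k: float(v)
                                           for k, v in raw["pricing"].items()})
        config = ModelConfig(
            name=str(raw.get("name", "scenario")),
            horizon_years=float(raw["horizon_years"]),
            cycle_length_years=float(raw["cycle_length_years"]),
            baseline_age=float(raw["baseline_age"]),
            initial_distribution=raw["initial_distribution"],
            discount_rate_annual=float(raw["discount_rate_annual"]),
            wtp_per_qaly=float(raw["wtp_per_qaly"]),
            transition=TransitionMatrix(raw["transition_matrix"]),
            background_mortality=BackgroundMortality(tuple(
                (b["age_low"], b["age_high"], b["p_noncv"])
                for b in raw["background_mortality"])),
            utilities=UtilityInputs(raw["utilities"]["u_by_state"],
                                    raw["utilities"]["disutility_by_state"]),
            arms=arms,
            distributions={name: _dist_from_dict(name, d)
                           for name, d in raw.get("distributions", {}).items()},
            pricing=pricing,
            notes=raw.get("notes", {}),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"config is missing or has a malformed field: {exc}") from exc
    if "n_cycles" in raw:
        declared = int(raw["n_cycles"])
        _require(declared == config.n_cycles,
                 f"n_cycles={declared} disagrees with horizon/cycle_length "
                 f"({config.n_cycles})")
    return config


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a scenario from a YAML file."""
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path} is not valid YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path} does not contain a mapping")
    return config_from_dict(raw)


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write a scenario back to YAML (round-trips bit-identically)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def base_case() -> ModelConfig:
    """The bundled published base-case scenario (2022 CNY)."""
    with resources.files("hfcua").joinpath("data/vericiguat_base_case.yaml").open(
            "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def parameter_table(config: ModelConfig):
    """Flattened parameter table (name, base, low, high, dist_kind, hyperparams).

    Returns a pandas DataFrame suitable for CSV export.
    """
    import pandas as pd

    from .sensitivity import base_value  # late import to avoid a cycle

    rows = []
    for name, dist in config.distributions.items():
        try:
            base = base_value(config, name)
        except KeyError:
            base = None
        hyper = _dist_to_dict(dist)
        hyper.pop("kind")
        hyper.pop("low", None)
        hyper.pop("high", None)
        rows.append({
            "name": name,
            "base": base,
            "low": dist.low,
            "high": dist.high,
            "dist_kind": dist.kind,
            "hyperparams": ";".join(f"{k}={v}" for k, v in hyper.items()),
        })
    return pd.DataFrame(rows, columns=["name", "base", "low", "high",
                                       "dist_kind", "hyperparams"])
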