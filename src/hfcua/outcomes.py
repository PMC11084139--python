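"""Arm aggregation, incremental cost-utility analysis and price thresholds."""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import bisect

from .config import ModelConfig, ValidationError
from .engine import CycleLedger, run_cohort

__all__ = [
    "ArmOutcome",
    "Dominance",
    "CUAResult",
    "arm_outcome",
    "summarize_ledgers",
    "compute_cua",
    "run_cua",
    "net_monetary_benefit",
    "price_threshold",
    "PriceThresholdResult",
    "cua_table",
]


@dataclass(frozen=True)
class ArmOutcome:
    """Totals for one arm: discounted cost and QALYs, undiscounted life-years."""

    arm_name: str
    total_cost: float
    total_qalys: float
    life_years: float

    def __post_init__(self) -> None:
        if min(self.total_cost, self.total_qalys, self.life_years) < 0:
            raise ValidationError("arm totals must be non-negative")


def summarize_ledgers(arm_name: str, ledgers: list[CycleLedger]) -> ArmOutcome:
    return ArmOutcome(
        arm_name=arm_name,
        total_cost=sum(l.disc_cost for l in ledgers),
        total_qalys=sum(l.disc_qaly for l in ledgers),
        life_years=sum(l.life_years for l in ledgers),
    )


def arm_outcome(config: ModelConfig, arm_name: str) -> ArmOutcome:
    """Run the cohort engine for one arm and aggregate its ledger."""
    _trace, ledgers = run_cohort(config, arm_name)
    return summarize_ledgers(arm_name, ledgers)


class Dominance(enum.Enum):
    NONE = "none"            # trade-off: ICUR vs WTP decides
    DOMINANT = "dominant"    # cheaper and more effective
    DOMINATED = "dominated"  # dearer and less effective
    EQUAL = "equal"          # identical cost and effect


@dataclass(frozen=True)
class CUAResult:
    """Incremental comparison of an intervention against a comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icur: float | None       # CNY per QALY; None when delta_effect == 0
    dominance: Dominance
    wtp: float
    cost_effective: bool


def compute_cua(intervention: ArmOutcome, comparator: ArmOutcome,
                wtp: float) -> CUAResult:
    """Incremental cost, effect, ICUR and the WTP decision rule.

    The intervention is cost-effective when it dominates, or when it buys
    additional QALYs at an ICUR at or below the willingness-to-pay.
    """
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.total_qalys - comparator.total_qalys
    icur = dc / de if de != 0 else None
    if dc == 0 and de == 0:
        dom = Dominance.EQUAL
    elif dc <= 0 and de >= 0:
        dom = Dominance.DOMINANT
    elif dc >= 0 and de <= 0:
        dom = Dominance.DOMINATED
    else:
        dom = Dominance.NONE
    if dom is Dominance.DOMINANT:
        decision = True
    elif dom in (Dominance.DOMINATED, Dominance.EQUAL):
        decision = False
    else:
        decision = de > 0 and icur is not None and icur <= wtp
    return CUAResult(intervention=intervention.arm_name,
                     comparator=comparator.arm_name,
                     delta_cost=dc, delta_effect=de, icur=icur,
                     dominance=dom, wtp=wtp, cost_effective=decision)


def run_cua(config: ModelConfig, intervention: str | None = None,
            comparator: str | None = None,
            wtp: float | None = None) -> tuple[ArmOutcome, ArmOutcome, CUAResult]:
    """Run both arms of a scenario and compare them.

    Defaults: the second configured arm is the intervention, the first the
    comparator (the bundled base case lists standard treatment first).
    """
    names = config.arm_names
    comparator = comparator or names[0]
    intervention = intervention or names[1]
    out_c = arm_outcome(config, comparator)
    out_i = arm_outcome(config, intervention)
    res = compute_cua(out_i, out_c, config.wtp_per_qaly if wtp is None else wtp)
    return out_i, out_c, res


def net_monetary_benefit(outcome: ArmOutcome, wtp: float) -> float:
    """NMB = wtp * QALYs - cost; higher is better at the given threshold."""
    if wtp < 0:
        raise ValidationError(f"wtp must be >= 0, got {wtp}")
    return wtp * outcome.total_qalys - outcome.total_cost


# ---------------------------------------------------------------------------
# Value-based price threshold
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriceThresholdResult:
    """Box price solving ICUR(price) = WTP, plus the verification run."""

    box_price_5mg: float
    wtp: float
    icur_at_price: float
    base_icur: float
    converged: bool
    note: str = ""


def _reprice(config: ModelConfig, intervention: str, p_5mg: float,
             reprice_titration: bool) -> ModelConfig:
    """Rebuild the intervention arm's drug cycle costs at a new 5 mg box price."""
    pricing = config.pricing
    arm = config.arm(intervention)
    first, later = pricing.cycle_costs(p_5mg)
    if not reprice_titration:
        first_base, _ = pricing.cycle_costs()
        first = first_base
    costs = replace(arm.costs,
                    c_arm_first_cycle=arm.costs.c_standard_cycle + first,
                    c_arm_later_cycle=arm.costs.c_standard_cycle + later)
    arms = dict(config.arms)
    arms[intervention] = replace(arm, costs=costs)
    return config.with_updates(arms=arms)


def price_threshold(config: ModelConfig, wtp: float,
                    intervention: str | None = None,
                    comparator: str | None = None,
                    reprice_titration: bool = True,
                    xtol: float = 0.01) -> PriceThresholdResult:
    """Find the 5 mg box price at which the ICUR equals the WTP.

    The 2.5 mg box price scales proportionally with the 5 mg box, and by
    default the titrated first cycle is repriced along with maintenance
    cycles.  The root is found by bisection on (0, current price]; because
    total cost is affine in the box price while QALYs are unaffected, the
    ICUR is strictly increasing in price and the root is unique.  If the
    scenario is already cost-effective at the current price, that price is
    returned unchanged.
    """
    if config.pricing is None:
        raise ValidationError("config has no pricing section")
    names = config.arm_names
    comparator = comparator or names[0]
    intervention = intervention or names[1]
    current = config.pricing.box_5mg_cny

    out_c = arm_outcome(config, comparator)

    def icur_at(p: float) -> float:
        repriced = _reprice(config, intervention, p, reprice_titration)
        out_i = arm_outcome(repriced, intervention)
        res = compute_cua(out_i, out_c, wtp)
        if res.icur is None:
            raise ValidationError("ICUR undefined: arms have equal QALYs")
        return res.icur

    base_icur = icur_at(current)
    if base_icur <= wtp:
        return PriceThresholdResult(
            box_price_5mg=current, wtp=wtp, icur_at_price=base_icur,
            base_icur=base_icur, converged=True,
            note="already cost-effective at the current price")

    lo = 1e-6
    icur_lo = icur_at(lo)
    if icur_lo > wtp:
        return PriceThresholdResult(
            box_price_5mg=lo, wtp=wtp, icur_at_price=icur_lo,
            base_icur=base_icur, converged=False,
            note=f"no root in (0, {current}]: ICUR at a near-zero price is "
                 f"{icur_lo:.2f}, above the WTP {wtp:.2f}")
    root = float(bisect(lambda p: icur_at(p) - wtp, lo, current, xtol=xtol))
    return PriceThresholdResult(box_price_5mg=root, wtp=wtp,
                                icur_at_price=icur_at(root),
                                base_icur=base_icur, converged=True)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def cua_table(intervention: ArmOutcome, comparator: ArmOutcome,
              result: CUAResult):
    """Headline results table (one row per arm, incrementals on the first).

    Monetary values and QALYs are rounded to 2 decimals, the reporting
    precision; pass the DataFrame to ``to_csv`` or ``to_string``.
    """
    import pandas as pd

    def row(o: ArmOutcome, inc: bool):
        return {
            "treatment": o.arm_name,
            "total_cost_cny": round(o.total_cost, 2),
            "qalys": round(o.total_qalys, 2),
            "mean_life_years": round(o.life_years, 2),
            "incremental_cost_cny": round(result.delta_cost, 2) if inc else None,
            "incremental_qaly": round(result.delta_effect, 2) if inc else None,
            "icur_cny_per_qaly": (round(result.icur, 2)
                                  if inc and result.icur is not None
                                  else (result.dominance.value if inc else None)),
        }

    return pd.DataFrame([row(intervention, True), row(comparator, False)])
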