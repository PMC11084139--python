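from dataclasses import replace

import numpy as np
import pytest

from hfcua import (
    Arm,
    BackgroundMortality,
    EventRates,
    TransitionMatrix,
    base_case,
    run_cua,
)


@pytest.fixture(scope="session")
def cfg():
    """The bundled published base-case scenario."""
    return base_case()


@pytest.fixture(scope="session")
def base_result(cfg):
    """(intervention outcome, comparator outcome, CUA result) for the base case."""
    return run_cua(cfg)


def zero_event_config(cfg, *, horizon_years=0.25, init=(1.0, 0.0, 0.0, 0.0),
                      identity_transition=True, discount=0.0):
    """Degenerate scenario: nobody dies, nobody is admitted, nobody moves."""
    arms = {
        name: replace(arm, events=EventRates(0.0, 0.0, 0.0))
        for name, arm in cfg.arms.items()
    }
    updates = dict(
        horizon_years=horizon_years,
        initial_distribution=np.array(init),
        discount_rate_annual=discount,
        arms=arms,
        background_mortality=BackgroundMortality(((0.0, 200.0, 0.0),)),
        distributions={},
    )
    if identity_transition:
        updates["transition"] = TransitionMatrix(np.eye(4))
    return cfg.with_updates(**updates)


def set_arm_events(cfg, arm_name, **events):
    arm = cfg.arm(arm_name)
    arms = dict(cfg.arms)
    arms[arm_name] = replace(arm, events=replace(arm.events, **events))
    return cfg.with_updates(arms=arms)
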