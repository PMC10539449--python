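import numpy as np
import pandas as pd
import pytest

from racquetvr import agent as ag
from racquetvr import design as dsn
from racquetvr import physics as phy


@pytest.fixture(scope="session")
def traj_normal():
    return phy.make_trajectory(phy.ELASTICITY_NORMAL)


@pytest.fixture(scope="session")
def traj_bouncy():
    return phy.make_trajectory(phy.ELASTICITY_BOUNCY)


@pytest.fixture(scope="session")
def baseline_trial():
    return dsn.make_baseline_block().trials[0]


@pytest.fixture(scope="session")
def noiseless_trial(baseline_trial, traj_normal):
    """One fully deterministic trial rendered with every noise source off."""
    params = ag.AgentParams.noiseless()
    rng = np.random.default_rng(0)
    return ag.generate_trial(baseline_trial, traj_normal,
                             ag.BeliefState(0.0), params, rng)


def make_long_table(rng, n_per_group=22, group_shift=0.0, cond_shift=0.0,
                    interaction=0.0, sd=1.0):
    """Balanced long-format outcome table for ANOVA tests."""
    rows = []
    for i in range(2 * n_per_group):
        group = "ASD" if i < n_per_group else "NT"
        base = rng.normal(0.0, sd)
        for cond in ("control", "cued"):
            val = base + rng.normal(0.0, sd)
            if group == "ASD":
                val += group_shift
                if cond == "cued":
                    val += interaction
            if cond == "cued":
                val += cond_shift
            rows.append({
                "participant_id": f"P{i:03d}", "group": group,
                "condition": cond, "outcome_name": "y", "value": val,
                "AQ_total": rng.normal(25, 8), "IUS_total": rng.normal(33, 10),
            })
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
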