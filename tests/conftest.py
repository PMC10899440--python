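"""Shared fixtures and the pure-Python likelihood oracle.

The oracle replays a trial log through the step-by-step :class:`AgentState`
API (softmax, mixture, lapse, delta rule, WM store/decay composed in Python)
and is deliberately independent of the JIT kernel that production code uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rlwm.agent import AgentState, RLWMParams, simulate_agent
from rlwm.task import SubjectDataset, TaskConfig, generate_schedule


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(TaskConfig(), seed=11)


@pytest.fixture(scope="session")
def two_block_schedule():
    cfg = TaskConfig(n_learning_blocks=2, set_sizes=(2, 5),
                     presentations=(12, 12), include_training=False)
    return generate_schedule(cfg, seed=5)


@pytest.fixture(scope="session")
def simulated_subject(default_schedule):
    params = RLWMParams(alpha=0.15, phi=0.25, rho=0.85, epsilon=0.12,
                        beta=8.0, K=3)
    return simulate_agent(params, default_schedule, seed=21, subject_id="s0")


def oracle_nll(params: RLWMParams, trials: pd.DataFrame) -> float:
    """Forward-pass NLL via the composed step-by-step agent operations."""
    total = 0.0
    df = trials[trials["block"] > 0]
    for _, block in df.groupby("block", sort=True):
        ns = int(block["set_size"].iloc[0])
        state = AgentState(ns, params)
        stim_index: dict[str, int] = {}
        for row in block.itertuples(index=False):
            if row.stimulus not in stim_index:
                stim_index[row.stimulus] = len(stim_index)
            s = stim_index[row.stimulus]
            if not bool(row.valid):
                continue
            p = state.choice_probabilities(s)
            total -= np.log(max(p[int(row.action)], 1e-12))
            state.update(s, int(row.action), float(row.reward))
    return total


@pytest.fixture(scope="session")
def oracle():
    return oracle_nll
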