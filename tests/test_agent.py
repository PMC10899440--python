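"""RLWM agent: policy construction, value updates, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rlwm import _kernel
from rlwm.agent import (AgentState, RLWMParams, mix_and_noise, rl_update,
                        simulate_agent, softmax_policy, wm_weight)
from rlwm.fitting import negative_log_likelihood
from rlwm.task import TaskConfig, compile_schedule, generate_schedule

UNIFORM = np.full(3, 1.0 / 3.0)


@pytest.mark.parametrize("rho,K,ns,expected", [
    (1.0, 5, 2, 1.0),        # capacity exceeds load
    (0.8, 3, 5, 0.48),       # 0.8 * 3/5
    (0.0, 3, 2, 0.0),        # no prior reliance on WM
])
def test_wm_weight(rho, K, ns, expected):
    assert wm_weight(rho, K, ns) == pytest.approx(expected)


def test_wm_weight_rejects_zero_set_size():
    with pytest.raises(ValueError):
        wm_weight(0.5, 3, 0)


def test_softmax_policy_cases():
    assert softmax_policy(UNIFORM, 7.3) == pytest.approx(UNIFORM)
    assert softmax_policy([1, 0, 0], 0.0) == pytest.approx(UNIFORM)
    # independently computed: exp(5*q)/sum at q=[.5,.3,.2]
    out = softmax_policy([0.5, 0.3, 0.2], 5.0)
    assert out == pytest.approx([0.6285, 0.2312, 0.1403], abs=1e-4)
    with pytest.raises(ValueError):
        softmax_policy([np.nan, 0, 0], 1.0)


def test_softmax_stable_for_huge_beta():
    out = softmax_policy([1.0, 0.0, 0.0], 1e6)
    assert np.isfinite(out).all() and out[0] == pytest.approx(1.0)


def test_mix_and_noise_cases():
    assert mix_and_noise([0.9, 0.05, 0.05], [0.2, 0.4, 0.4], 0.3, 1.0) == \
        pytest.approx(UNIFORM)
    pi_rl = np.array([0.2, 0.5, 0.3])
    assert mix_and_noise(UNIFORM, pi_rl, 0.0, 0.0) == pytest.approx(pi_rl)
    out = mix_and_noise([0.8, 0.1, 0.1], [0.4, 0.3, 0.3], 0.5, 0.1)
    assert out == pytest.approx([0.5733, 0.2133, 0.2133], abs=1e-4)
    with pytest.raises(ValueError):
        mix_and_noise([0.5, 0.5, 0.5], UNIFORM, 0.5, 0.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=3, max_size=3),
       st.floats(0, 60), st.floats(0, 1), st.floats(0, 1))
def test_policy_pipeline_emits_distribution(q, beta, p_wm, eps):
    pi = mix_and_noise(softmax_policy(q, beta), softmax_policy(q[::-1], beta),
                       p_wm, eps)
    assert pi.min() >= 0
    assert abs(pi.sum() - 1.0) < 1e-12


def test_rl_update():
    assert rl_update(1 / 3, 1.0, 0.1) == pytest.approx(0.4)
    assert rl_update(0.5, 0.0, 1.0) == 0.0
    assert rl_update(0.77, 0.77, 0.42) == pytest.approx(0.77)  # zero RPE


def test_wm_store_and_decay():
    params = RLWMParams(0.1, 0.5, 0.9, 0.0, 8.0, 3)
    state = AgentState(2, params)
    state.wm_store(0, 1, 1.0)
    assert state.q_wm[0, 1] == 1.0
    state.wm_store(0, 1, 1.0)  # idempotent
    assert state.q_wm[0, 1] == 1.0
    state.wm_decay_step()
    assert state.q_wm[0, 1] == pytest.approx(2 / 3)  # 1 + 0.5*(1/3 - 1)
    # phi = 0 leaves the table alone; phi = 1 collapses it to Q0
    s2 = AgentState(2, RLWMParams(0.1, 0.0, 0.9, 0.0, 8.0, 3))
    s2.wm_store(1, 0, 1.0)
    before = s2.q_wm.copy()
    s2.wm_decay_step()
    assert (s2.q_wm == before).all()
    s3 = AgentState(2, RLWMParams(0.1, 1.0, 0.9, 0.0, 8.0, 3))
    s3.wm_store(1, 0, 1.0)
    s3.wm_decay_step()
    assert s3.q_wm == pytest.approx(np.full((2, 3), 1 / 3))


def test_unknown_stimulus_rejected():
    state = AgentState(2, RLWMParams(0.1, 0.1, 0.5, 0.1, 8.0, 3))
    with pytest.raises(ValueError):
        state.choice_probabilities(2)
    with pytest.raises(ValueError):
        state.wm_store(5, 0, 1.0)


def test_fresh_block_probabilities_uniform():
    state = AgentState(4, RLWMParams(0.3, 0.2, 0.9, 0.0, 17.0, 2))
    for s in range(4):
        assert state.choice_probabilities(s) == pytest.approx(UNIFORM)


def test_full_lapse_is_uniform_regardless_of_history():
    state = AgentState(2, RLWMParams(0.5, 0.0, 1.0, 1.0, 50.0, 5))
    state.update(0, 1, 1.0)
    assert state.choice_probabilities(0) == pytest.approx(UNIFORM)


def test_one_shot_wm_learning_dominates():
    # perfect WM: after one rewarded trial the action is near-certain
    params = RLWMParams(alpha=0.0, phi=0.0, rho=1.0, epsilon=0.0, beta=100.0, K=5)
    state = AgentState(2, params)
    state.update(0, 2, 1.0)
    p = state.choice_probabilities(0)
    assert p[2] > 0.999


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_value_tables_stay_bounded(seed):
    """Q_WM and Q_RL remain in [0, 1] under any update sequence."""
    rng = np.random.default_rng(seed)
    params = RLWMParams(alpha=rng.uniform(0, 1), phi=rng.uniform(0, 1),
                        rho=rng.uniform(0, 1), epsilon=rng.uniform(0, 1),
                        beta=rng.uniform(0.1, 40), K=int(rng.integers(1, 6)))
    state = AgentState(3, params)
    for _ in range(60):
        state.update(int(rng.integers(3)), int(rng.integers(3)),
                     float(rng.integers(2)))
        assert (state.q_wm >= 0).all() and (state.q_wm <= 1).all()
        assert (state.q_rl >= 0).all() and (state.q_rl <= 1).all()


def test_kernel_matches_pure_python_oracle(two_block_schedule, oracle):
    """The JIT likelihood equals the composed step-by-step agent operations."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        params = RLWMParams(*rng.uniform(0, 1, 4), float(rng.uniform(0.5, 20)),
                            int(rng.integers(1, 6)))
        sim = RLWMParams(0.2, 0.2, 0.8, 0.15, 8.0, 3)
        ds = simulate_agent(sim, two_block_schedule, seed=int(rng.integers(2**31)))
        nll, _ = negative_log_likelihood(params, ds)
        assert nll == pytest.approx(oracle(params, ds.trials), abs=1e-9)


def test_simulation_determinism(default_schedule):
    params = RLWMParams(0.2, 0.3, 0.8, 0.1, 8.0, 3)
    a = simulate_agent(params, default_schedule, seed=5)
    b = simulate_agent(params, default_schedule, seed=5)
    c = simulate_agent(params, default_schedule, seed=6)
    assert a.trials.equals(b.trials)
    assert not a.trials.equals(c.trials)


def test_chance_accuracy_under_full_lapse(default_schedule):
    params = RLWMParams(0.2, 0.2, 0.8, 1.0, 8.0, 3)
    accs = [simulate_agent(params, default_schedule, seed=s).learning_trials["reward"].mean()
            for s in range(200)]
    se = np.sqrt((1 / 3) * (2 / 3) / (432 * 200))
    assert abs(np.mean(accs) - 1 / 3) < 3 * se


def test_perfect_wm_accuracy_after_first_reward(default_schedule):
    params = RLWMParams(alpha=0.0, phi=0.0, rho=1.0, epsilon=0.0, beta=100.0, K=5)
    ds = simulate_agent(params, default_schedule, seed=8)
    # once the correct action has been found it is never lost
    key = ["block", "stimulus"]
    first_hit = ds.trials[ds.trials["reward"] == 1].groupby(key)["iteration"].min()
    for (blk, stim), t0 in first_hit.items():
        after = ds.trials[(ds.trials["block"] == blk) &
                          (ds.trials["stimulus"] == stim) &
                          (ds.trials["iteration"] > t0)]
        assert (after["reward"] == 1).all()


def test_empirical_frequencies_match_policy(two_block_schedule):
    """Simulated choice frequencies agree with the per-trial policies
    computed along each agent's realized history (3 MC SEs, 2000 agents)."""
    from rlwm.validation import likelihood_simulation_consistency
    res = likelihood_simulation_consistency(n_agents=2000, seed=4)
    assert res["max_abs_z"] <= 3.5  # 168 comparisons; modest multiplicity slack


def test_setsize_monotonicity_wm_dominant():
    """A WM-dominated, capacity-2 agent learns worse at larger set sizes."""
    from rlwm.validation import setsize_effect
    res = setsize_effect(n_agents=150, seed=2)
    acc = res["late_accuracy"]
    assert all(acc[a] >= acc[b] for a, b in zip((2, 3, 4), (3, 4, 5)))
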