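"""The RLWM agent: a capacity-limited working-memory policy mixed with a
delta-rule reinforcement-learning policy.

The model holds two stimulus x action value tables per block.  The RL table
updates incrementally at learning rate ``alpha``; the WM table stores the
last feedback exactly (learning rate 1) but decays every trial toward the
uninformative initial value ``Q0 = 1/3`` at rate ``phi``.  Both tables feed
softmax policies (shared inverse temperature ``beta``) that are mixed with
weight ``P_WM = rho * min(1, K / ns)`` -- working memory dominates while the
block's set size ``ns`` fits within capacity ``K`` -- and the mixed policy is
blended with a uniform lapse at rate ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel
from .task import SubjectDataset, TaskSchedule, compile_schedule

N_ACTIONS = 3
Q0 = 1.0 / 3.0

PARAM_NAMES = ("alpha", "phi", "rho", "epsilon", "beta", "K")


@dataclass(frozen=True)
class RLWMParams:
    """Free parameters of the RLWM agent.

    alpha    RL learning rate, in [0, 1]
    phi      WM decay (forgetting) rate, in [0, 1]
    rho      WM prior weight (maximum WM mixture share), in [0, 1]
    epsilon  undirected (lapse) noise, in [0, 1]
    beta     softmax inverse temperature, > 0
    K        WM capacity in items, integer >= 1
    """

    alpha: float
    phi: float
    rho: float
    epsilon: float
    beta: float = 8.0
    K: int = 3

    def __post_init__(self) -> None:
        for name in ("alpha", "phi", "rho", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if not (int(self.K) == self.K and self.K >= 1):
            raise ValueError("K must be an integer >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["K"] = int(d["K"])
        return d

    @staticmethod
    def from_dict(d: dict) -> "RLWMParams":
        return RLWMParams(**{k: d[k] for k in PARAM_NAMES})

    def as_tuple(self) -> tuple:
        return (self.alpha, self.phi, self.rho, self.epsilon, float(self.beta), float(self.K))


def wm_weight(rho: float, K: int, ns: int) -> float:
    """Mixture weight of the WM policy: ``rho * min(1, K / ns)``."""
    if ns < 1:
        raise ValueError("set size must be >= 1")
    if not 0.0 <= rho <= 1.0 or K < 1:
        raise ValueError("rho in [0,1] and K >= 1 required")
    return rho * min(1.0, K / ns)


def softmax_policy(q_row: np.ndarray, beta: float) -> np.ndarray:
    """Softmax with max-subtraction; ``beta = 0`` yields the uniform policy."""
    q = np.asarray(q_row, dtype=float)
    if np.any(np.isnan(q)):
        raise ValueError("NaN action values")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    z = beta * (q - q.max())
    e = np.exp(z)
    return e / e.sum()


def mix_and_noise(pi_wm: np.ndarray, pi_rl: np.ndarray,
                  p_wm: float, epsilon: float) -> np.ndarray:
    """Mix the two policies, then blend with the uniform lapse policy."""
    pi_wm = np.asarray(pi_wm, dtype=float)
    pi_rl = np.asarray(pi_rl, dtype=float)
    for pi in (pi_wm, pi_rl):
        if pi.min() < -1e-12 or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("inputs must be probability distributions")
    if not (0.0 <= p_wm <= 1.0 and 0.0 <= epsilon <= 1.0):
        raise ValueError("p_wm and epsilon must be in [0, 1]")
    pi = p_wm * pi_wm + (1.0 - p_wm) * pi_rl
    return (1.0 - epsilon) * pi + epsilon / len(pi)


def rl_update(q_sa: float, reward: float, alpha: float) -> float:
    """Delta rule: move the value toward the reward by the prediction error."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha outside [0, 1]")
    delta = reward - q_sa  # reward prediction error
    return q_sa + alpha * delta


class AgentState:
    """Per-block value tables of one RLWM agent (step-by-step API).

    This pure-Python implementation mirrors the JIT kernel trial for trial;
    it is the reference for single-trial inspection and for cross-checking
    the kernel in tests.
    """

    def __init__(self, set_size: int, params: RLWMParams):
        if set_size < 1:
            raise ValueError("set size must be >= 1")
        self.params = params
        self.set_size = set_size
        self.q_rl = np.full((set_size, N_ACTIONS), Q0)
        self.q_wm = np.full((set_size, N_ACTIONS), Q0)
        self.p_wm = wm_weight(params.rho, params.K, set_size)

    def _check_stim(self, stimulus: int) -> None:
        if not 0 <= stimulus < self.set_size:
            raise ValueError(f"stimulus {stimulus} not in block (ns={self.set_size})")

    def choice_probabilities(self, stimulus: int) -> np.ndarray:
        """Policy for the next choice on ``stimulus`` given current values."""
        self._check_stim(stimulus)
        pi_wm = softmax_policy(self.q_wm[stimulus], self.params.beta)
        pi_rl = softmax_policy(self.q_rl[stimulus], self.params.beta)
        return mix_and_noise(pi_wm, pi_rl, self.p_wm, self.params.epsilon)

    def wm_store(self, stimulus: int, action: int, reward: float) -> None:
        """One-shot WM storage: the entry becomes the reward exactly."""
        self._check_stim(stimulus)
        self.q_wm[stimulus, action] = reward

    def wm_decay_step(self) -> None:
        """Pull every WM entry toward Q0 by a fraction ``phi``."""
        self.q_wm += self.params.phi * (Q0 - self.q_wm)

    def update(self, stimulus: int, action: int, reward: float) -> None:
        """Feedback processing: RL delta rule, WM store, then WM decay."""
        self._check_stim(stimulus)
        self.q_rl[stimulus, action] = rl_update(self.q_rl[stimulus, action],
                                                reward, self.params.alpha)
        self.wm_store(stimulus, action, reward)
        self.wm_decay_step()


def trial_choice_probabilities(state: AgentState, params: RLWMParams,
                               stimulus: int) -> np.ndarray:
    if params is not state.params:
        state.params = params
        state.p_wm = wm_weight(params.rho, params.K, state.set_size)
    return state.choice_probabilities(stimulus)


def simulate_agent(params: RLWMParams, schedule: TaskSchedule, seed: int,
                   subject_id: str = "sim",
                   return_probs: bool = False) -> SubjectDataset:
    """Play the schedule generatively; deterministic under a fixed seed.

    Choices are sampled from the per-trial policy; value tables reset at each
    block start.  The result carries one trial record per scheduled trial.
    """
    arrays = compile_schedule(schedule)
    T = len(arrays["stim"])
    uniforms = np.random.default_rng(seed).random(T)
    actions = np.empty(T, dtype=np.int64)
    rewards = np.empty(T, dtype=np.float64)
    probs = np.empty((T, 3), dtype=np.float64)
    a, p, r, e, b, k = params.as_tuple()
    _kernel.simulate_forward(a, p, r, e, b, k,
                             arrays["stim"], arrays["set_size"], arrays["new_block"],
                             arrays["correct"], uniforms, actions, rewards, probs)
    # within-block trial index
    trial_in_block = np.arange(T) - np.maximum.accumulate(
        np.where(arrays["new_block"], np.arange(T), 0))
    df = pd.DataFrame({
        "subject_id": subject_id,
        "block": arrays["block"],
        "trial": trial_in_block,
        "set_size": arrays["set_size"],
        "stimulus": arrays["stim_name"],
        "iteration": arrays["iteration"],
        "action": actions,
        "correct_action": arrays["correct"],
        "reward": rewards.astype(np.int64),
        "rt_ms": np.nan,
        "valid": True,
    })
    ds = SubjectDataset(subject_id=subject_id, trials=df, params=params)
    if return_probs:
        return ds, probs
    return ds
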