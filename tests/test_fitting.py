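"""Likelihood evaluation and maximum-likelihood estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from rlwm.agent import RLWMParams, simulate_agent
from rlwm.fitting import (FitConfig, LN3, RLWMEstimator, default_param_sampler,
                          fit_quality_analysis, fit_subject,
                          negative_log_likelihood, parameter_recovery)
from rlwm.task import TaskConfig, generate_schedule


def test_uniform_policy_nll_is_T_ln3(simulated_subject):
    params = RLWMParams(0.4, 0.3, 0.6, 1.0, 5.0, 2)
    nll, chosen = negative_log_likelihood(params, simulated_subject)
    T = int(np.isfinite(chosen).sum())
    assert nll == pytest.approx(T * LN3, abs=1e-9)
    assert np.nanmin(chosen) == pytest.approx(1 / 3) == np.nanmax(chosen)


def _three_trial_frame():
    # ns=2 block: s1 chosen a0 rewarded twice, then s2 chosen a1 unrewarded
    return pd.DataFrame({
        "subject_id": "h", "block": 1, "trial": [0, 1, 2], "set_size": 2,
        "stimulus": ["s1", "s1", "s2"], "iteration": [1, 2, 1],
        "action": [0, 0, 1], "correct_action": [0, 0, 2],
        "reward": [1, 1, 0], "rt_ms": np.nan, "valid": True,
    })


def test_three_trial_hand_worked_nll():
    """Step-by-step hand computation of the forward pass.

    alpha=0.5, phi=0, rho=0.5, eps=0, beta=2, K=3 on an ns=2 block.
    Trial 1: all values at Q0 -> p = 1/3.  Updates: Q_RL(s1,a0) = 2/3,
    Q_WM(s1,a0) = 1.  Trial 2 (s1 again): P_WM = 0.5*min(1, 3/2) = 0.5;
    pi_WM(a0) = e^2 / (e^2 + 2 e^(2/3)); pi_RL(a0) = e^(4/3) / (e^(4/3)
    + 2 e^(2/3)); p = their mean.  Trial 3: fresh stimulus -> 1/3.
    """
    e2, e23, e43 = math.exp(2.0), math.exp(2 / 3), math.exp(4 / 3)
    p2 = 0.5 * (e2 / (e2 + 2 * e23)) + 0.5 * (e43 / (e43 + 2 * e23))
    expected = 2 * LN3 - math.log(p2)
    params = RLWMParams(alpha=0.5, phi=0.0, rho=0.5, epsilon=0.0, beta=2.0, K=3)
    nll, chosen = negative_log_likelihood(params, _three_trial_frame())
    assert nll == pytest.approx(expected, abs=1e-12)
    assert nll == pytest.approx(2.7521973, abs=1e-6)
    assert chosen == pytest.approx([1 / 3, p2, 1 / 3])


def test_probabilities_floored_by_lapse(simulated_subject):
    params = RLWMParams(0.2, 0.2, 0.9, 0.3, 20.0, 3)
    _, chosen = negative_log_likelihood(params, simulated_subject)
    finite = chosen[np.isfinite(chosen)]
    assert (finite >= 0.3 / 3).all() and (finite <= 1.0).all()


def test_invalid_trials_skipped():
    df = _three_trial_frame()
    extra = df.iloc[[2]].copy()
    extra = extra.astype({"action": float, "reward": float})
    extra.loc[:, ["trial", "iteration"]] = [[3, 2]]
    extra.loc[:, "action"] = np.nan
    extra.loc[:, "reward"] = np.nan
    extra.loc[:, "valid"] = False
    df2 = pd.concat([df, extra], ignore_index=True)
    params = RLWMParams(0.5, 0.0, 0.5, 0.0, 2.0, 3)
    nll_a, _ = negative_log_likelihood(params, df)
    nll_b, chosen_b = negative_log_likelihood(params, df2)
    assert nll_b == pytest.approx(nll_a)
    assert np.isnan(chosen_b[-1])


def test_empty_dataset_raises():
    with pytest.raises(ValueError):
        negative_log_likelihood(RLWMParams(0.1, 0.1, 0.5, 0.1),
                                _three_trial_frame().iloc[0:0])


def test_fit_never_worse_than_uniform(default_schedule):
    noisy = RLWMParams(0.5, 0.5, 0.5, 1.0, 8.0, 3)
    ds = simulate_agent(noisy, default_schedule, seed=3)
    fr = fit_subject(ds, FitConfig(n_starts=2, k_grid=(3,), fixed={"beta": 8.0}),
                     seed=0)
    assert fr.nll <= fr.n_trials * LN3 + 1e-6


def test_fit_determinism(simulated_subject):
    cfg = FitConfig(n_starts=3, k_grid=(3,), fixed={"beta": 8.0})
    a = fit_subject(simulated_subject, cfg, seed=4)
    b = fit_subject(simulated_subject, cfg, seed=4)
    assert a.params == b.params and a.nll == b.nll


def test_fit_beats_any_fixed_candidate(simulated_subject):
    """Optimization can only improve on a directly evaluated candidate."""
    cfg = FitConfig(n_starts=5, k_grid=(3,), fixed={"beta": 8.0})
    fr = fit_subject(simulated_subject, cfg, seed=1)
    rng = np.random.default_rng(0)
    for _ in range(10):
        cand = RLWMParams(*rng.uniform(0, 1, 4), 8.0, 3)
        nll_c, _ = negative_log_likelihood(cand, simulated_subject)
        assert fr.nll <= nll_c + 1e-9
    # and on the generating parameters themselves
    nll_true, _ = negative_log_likelihood(simulated_subject.params, simulated_subject)
    assert fr.nll <= nll_true + 1e-9


def test_estimator_sklearn_interface(simulated_subject):
    est = RLWMEstimator(n_starts=2, k_grid=(3,), fixed={"beta": 8.0},
                        random_state=0)
    assert est.get_params()["n_starts"] == 2
    est.set_params(n_starts=3)
    est.fit(simulated_subject)
    assert hasattr(est, "params_") and est.nll_ > 0
    probs = est.predict_proba(simulated_subject)
    assert np.nansum(np.log(probs)) == pytest.approx(-est.nll_)
    assert est.score(simulated_subject) == pytest.approx(-est.nll_ / est.n_trials_)
    from sklearn.base import clone
    clone(est)  # must be cloneable for model selection


def test_recovery_report_shape_and_determinism():
    cfg = FitConfig(n_starts=2, k_grid=(3,), fixed={"beta": 8.0}, max_iter=60)
    a = parameter_recovery(4, seed=9, fit_config=cfg)
    b = parameter_recovery(4, seed=9, fit_config=cfg)
    assert len(a.table) == 4
    assert a.table.equals(b.table)
    assert a.stats["pearson_r"].between(-1, 1).all()
    with pytest.raises(ValueError):
        parameter_recovery(1, seed=0)


def test_recovery_in_wm_dominant_regime():
    """In the behaviorally plausible regime (high WM prior, modest lapse) the
    decay and lapse parameters are well identified."""
    def sampler(rng):
        return RLWMParams(rng.uniform(0.05, 0.6), rng.uniform(0.05, 0.6),
                          rng.uniform(0.6, 1.0), rng.uniform(0.0, 0.4), 8.0, 3)
    rep = parameter_recovery(30, param_sampler=sampler, seed=11,
                             fit_config=FitConfig(n_starts=5, k_grid=(3,),
                                                  fixed={"beta": 8.0}))
    assert rep.correlation("phi") >= 0.6
    assert rep.correlation("epsilon") >= 0.6
    assert rep.n_failed == 0


def test_recovery_improves_with_more_blocks():
    """phi/epsilon identification degrades gracefully on shorter sessions."""
    def sampler(rng):
        return RLWMParams(rng.uniform(0.05, 0.6), rng.uniform(0.05, 0.6),
                          rng.uniform(0.6, 1.0), rng.uniform(0.0, 0.4), 8.0, 3)
    short = TaskConfig(n_learning_blocks=2, set_sizes=(3, 4),
                       presentations=(12, 12), include_training=False)
    cfg = FitConfig(n_starts=4, k_grid=(3,), fixed={"beta": 8.0})
    rep2 = parameter_recovery(25, param_sampler=sampler, schedule_config=short,
                              seed=13, fit_config=cfg)
    rep10 = parameter_recovery(25, param_sampler=sampler, seed=13, fit_config=cfg)
    assert rep2.correlation("phi") < rep10.correlation("phi")
    assert rep2.correlation("epsilon") < rep10.correlation("epsilon")


def test_fit_quality_analysis(default_schedule):
    rng = np.random.default_rng(2)
    fits, labels = [], []
    for grp, eps_range in (("A", (0.0, 0.15)), ("B", (0.45, 0.7))):
        for i in range(6):
            params = RLWMParams(0.2, 0.2, 0.85, float(rng.uniform(*eps_range)),
                                8.0, 3)
            ds = simulate_agent(params, default_schedule,
                                seed=int(rng.integers(2**31)))
            fr = fit_subject(ds, FitConfig(n_starts=2, k_grid=(3,),
                                           fixed={"beta": 8.0}), seed=i)
            fits.append(fr)
            labels.append(grp)
    rep = fit_quality_analysis(fits, labels)
    # more lapse -> worse attainable fit: positive eps/NLL correlation, and
    # the high-noise group has the higher per-trial NLL
    assert rep["epsilon_vs_nll"]["r"] > 0
    assert rep["epsilon_vs_loglik"]["r"] == pytest.approx(-rep["epsilon_vs_nll"]["r"])
    t = rep["group_nll_ttest"]
    assert (t["t"] < 0) == (t["groups"][0] == "A")

    with pytest.raises(ValueError):
        fit_quality_analysis(fits[:2], labels[:2])


def test_fit_quality_flags_constant_epsilon(simulated_subject):
    fr = fit_subject(simulated_subject,
                     FitConfig(n_starts=1, k_grid=(3,), fixed={"beta": 8.0}),
                     seed=0)
    import dataclasses
    same = [dataclasses.replace(fr, subject_id=f"s{i}") for i in range(4)]
    rep = fit_quality_analysis(same, ["A", "A", "B", "B"])
    assert rep["epsilon_constant"] is True
    assert rep["group_nll_ttest"]["t"] == 0.0
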