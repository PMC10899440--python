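"""Self-validation experiments for the RLWM pipeline.

Each function runs one end-to-end check of the package on synthetic data at a
stated problem size and returns plain numbers; the test suite asserts on
them and ``scripts/acceptance.py`` reports them.  Problem sizes follow the
package's validation protocol (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .agent import RLWMParams, simulate_agent
from .cohort import CohortConfig, GroupSpec, default_group_specs, generate_cohort
from .curves import compute_learning_curves, fit_logistic_growth, logistic_growth
from .fitting import (FitConfig, LN3, fit_subject, negative_log_likelihood,
                      parameter_recovery)
from .stats import compare_groups, rt_parameter_regression, summarize_subject
from .task import TaskConfig, compile_schedule, generate_schedule
from . import _kernel


def two_block_config() -> TaskConfig:
    """Small two-block schedule (ns 2 and 5) used by forward-model checks."""
    return TaskConfig(n_learning_blocks=2, set_sizes=(2, 5),
                      presentations=(12, 12), include_training=False)


def likelihood_simulation_consistency(n_agents: int = 10_000, seed: int = 0,
                                      params: Optional[RLWMParams] = None) -> dict:
    """Simulate many agents on one schedule and compare, at every trial, the
    empirical choice frequencies against the mean forward-pass policy.

    Each agent's trial-t policy depends on its own realized history, so the
    reference is the across-agent mean policy and the Monte-Carlo SE is
    ``sqrt(sum p(1-p)) / N``.  Returns the largest |z| over trials x actions.
    """
    params = params or RLWMParams(alpha=0.2, phi=0.2, rho=0.8, epsilon=0.1,
                                  beta=8.0, K=3)
    schedule = generate_schedule(two_block_config(), seed=seed)
    arrays = compile_schedule(schedule)
    T = len(arrays["stim"])
    counts = np.zeros((T, 3))
    p_sum = np.zeros((T, 3))
    p_sq = np.zeros((T, 3))
    rng = np.random.default_rng(seed + 1)
    a, ph, r, e, b, k = params.as_tuple()
    actions = np.empty(T, dtype=np.int64)
    rewards = np.empty(T, dtype=np.float64)
    probs = np.empty((T, 3), dtype=np.float64)
    for _ in range(n_agents):
        uniforms = rng.random(T)
        _kernel.simulate_forward(a, ph, r, e, b, k,
                                 arrays["stim"], arrays["set_size"],
                                 arrays["new_block"], arrays["correct"],
                                 uniforms, actions, rewards, probs)
        counts[np.arange(T), actions] += 1
        p_sum += probs
        p_sq += probs * (1.0 - probs)
    freq = counts / n_agents
    mean_p = p_sum / n_agents
    se = np.sqrt(p_sq) / n_agents  # SE of the mean of independent Bernoullis
    z = np.abs(freq - mean_p) / np.maximum(se, 1e-12)
    return {"max_abs_z": float(z.max()), "n_agents": n_agents, "n_trials": T,
            "max_abs_gap": float(np.abs(freq - mean_p).max())}


def uniform_policy_checks(seed: int = 0) -> dict:
    """Analytic limits: at epsilon = 1 the NLL is T*ln(3) exactly, and a fresh
    block's choice probabilities are exactly uniform."""
    params = RLWMParams(alpha=0.3, phi=0.2, rho=0.7, epsilon=1.0, beta=5.0, K=3)
    schedule = generate_schedule(two_block_config(), seed=seed)
    ds = simulate_agent(params, schedule, seed=seed + 1)
    nll, chosen = negative_log_likelihood(params, ds)
    T = int(np.isfinite(chosen).sum())
    # fresh-block probabilities under a non-degenerate parameter set
    probe = RLWMParams(alpha=0.2, phi=0.1, rho=0.9, epsilon=0.05, beta=10.0, K=3)
    _, probs = simulate_agent(probe, schedule, seed=seed + 2, return_probs=True)
    arrays = compile_schedule(schedule)
    fresh = probs[arrays["new_block"]]
    return {"nll_gap": float(abs(nll - T * LN3)), "n_trials": T,
            "fresh_block_max_dev": float(np.abs(fresh - 1.0 / 3.0).max())}


def recovery_experiment(n_subjects: int = 100, seed: int = 7,
                        n_starts: int = 5) -> dict:
    """Uniform-parameter recovery on the default 10-block schedule
    (beta = 8 and K = 3 fixed, as in the reported four-parameter analysis)."""
    fit_config = FitConfig(n_starts=n_starts, k_grid=(3,), fixed={"beta": 8.0})
    report = parameter_recovery(n_subjects, seed=seed, fit_config=fit_config)
    out: dict = {"n_subjects": n_subjects, "n_failed": report.n_failed}
    for name in ("alpha", "phi", "rho", "epsilon"):
        out[f"r_{name}"] = float(report.stats.loc[name, "pearson_r"])
        out[f"bias_{name}"] = float(report.stats.loc[name, "bias"])
        out[f"rmse_{name}"] = float(report.stats.loc[name, "rmse"])
    return out


def setsize_effect(n_agents: int = 500, seed: int = 0,
                   late_window: int = 6) -> dict:
    """WM-limited agent (high prior, capacity 2): late-iteration accuracy
    should fall as the set size grows past capacity.

    "Late" is the second half of the balanced presentation domain (the last
    ``late_window`` of 12 iterations), the asymptotic portion of the curve.
    """
    params = RLWMParams(alpha=0.05, phi=0.05, rho=0.95, epsilon=0.02,
                        beta=25.0, K=2)
    ss = np.random.SeedSequence(seed)
    frames = []
    for i in range(n_agents):
        s1, s2 = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
        schedule = generate_schedule(TaskConfig(), s1)
        ds = simulate_agent(params, schedule, s2, subject_id=f"ws{i:03d}")
        frames.append(ds.learning_trials)
    curves = compute_learning_curves(pd.concat(frames, ignore_index=True))
    t_max = int(curves["iteration"].max())
    late = curves[curves["iteration"] > t_max - late_window]
    acc = {int(ns): float(g["mean_correct"].mean())
           for ns, g in late.groupby("set_size")}
    ordered = [acc[ns] for ns in sorted(acc)]
    return {"late_accuracy": acc, "n_agents": n_agents,
            "strictly_decreasing": bool(all(x > y for x, y in zip(ordered, ordered[1:])))}


def growth_exactness() -> dict:
    """Noiseless in-class data must be recovered almost exactly, and a flat
    curve must be flagged degenerate instead of mis-fit."""
    t = np.arange(1, 14)
    A, B, k = 0.8, 5.0, 0.6
    fit = fit_logistic_growth(t, logistic_growth(t, A, B, k))
    rel = max(abs(fit.A - A) / A, abs(fit.B - B) / B, abs(fit.k - k) / k)
    flat = fit_logistic_growth(t, np.full_like(t, 0.5, dtype=float))
    return {"max_rel_error": float(rel),
            "flat_flagged_degenerate": bool(flat.degenerate),
            "flat_A": float(flat.A), "n_points": len(t)}


PATTERN_EFFECTS = (
    ("young_mid", "alpha", True), ("young_mid", "phi", True),
    ("young_mid", "epsilon", True), ("young_mid", "rho", False),
    ("normal_mci", "epsilon", True), ("normal_mci", "alpha", False),
    ("normal_mci", "phi", False), ("normal_mci", "rho", False),
)


def cohort_pattern_experiment(n_per_group: int = 100, n_replicates: int = 20,
                              seed: int = 0, n_starts: int = 2,
                              alpha_level: float = 0.05) -> dict:
    """End-to-end qualitative reproduction at scale.

    Each replicate: generate a cohort (n per group), exclude chance-level
    subjects, fit every subject (beta/K fixed, reduced starts), and test each
    parameter between young vs. normal middle-aged and normal vs. MCI.  A
    replicate reproduces the target pattern when the young-vs-middle
    difference is significant for alpha, phi and epsilon but not the prior,
    and the normal-vs-MCI difference is significant for epsilon only.
    """
    fit_config = FitConfig(n_starts=n_starts, k_grid=(3,), fixed={"beta": 8.0},
                           max_iter=100)
    ss = np.random.SeedSequence(seed)
    effect_hits = {key: 0 for key in PATTERN_EFFECTS}
    n_success = 0
    for rep in range(n_replicates):
        rep_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        groups = default_group_specs(n_young=n_per_group, n_normal=n_per_group,
                                     n_mci=n_per_group)
        cohort = generate_cohort(CohortConfig(groups=groups, seed=rep_seed))
        kept = [d for d in cohort
                if summarize_subject(d).accuracy >= 0.33]
        fit_rng = np.random.SeedSequence(rep_seed + 1)
        fits = {}
        for d in kept:
            fseed = int(fit_rng.spawn(1)[0].generate_state(1)[0] % (2**31))
            fits[d.subject_id] = fit_subject(d, fit_config, seed=fseed)
        table = pd.DataFrame([
            {"group": d.group, **fits[d.subject_id].params.to_dict()}
            for d in kept])
        ok = True
        for contrast, param, expect_sig in PATTERN_EFFECTS:
            if contrast == "young_mid":
                pair = ("young", "normal_mid")
            else:
                pair = ("normal_mid", "mci_mid")
            rep_stat = compare_groups(
                {g: table.loc[table["group"] == g, param].to_numpy() for g in pair},
                family_size=1)
            sig = rep_stat.p_raw < alpha_level
            hit = sig == expect_sig
            effect_hits[(contrast, param, expect_sig)] += hit
            ok = ok and hit
        n_success += ok
    out = {"pattern_rate": n_success / n_replicates,
           "n_replicates": n_replicates, "n_per_group": n_per_group}
    for (contrast, param, expect), hits in effect_hits.items():
        tag = "sig" if expect else "ns"
        out[f"rate_{contrast}_{param}_{tag}"] = hits / n_replicates
    return out


def rt_regression_recovery(n_subjects: int = 500, seed: int = 0,
                           noise_sd: float = 20.0) -> dict:
    """Generate a large young group with the configured RT coefficients and
    check that the RT ~ phi + prior regression recovers them within 2 SE."""
    base = default_group_specs()[0]
    spec = dataclasses.replace(base, n=n_subjects, rt_noise_sd=noise_sd,
                               rt_error_increment=0.0)
    cohort = generate_cohort(CohortConfig(groups=[spec], seed=seed))
    mean_rt = [d.learning_trials["rt_ms"].mean() for d in cohort]
    phis = [d.params.phi for d in cohort]
    rhos = [d.params.rho for d in cohort]
    reg = rt_parameter_regression(mean_rt, phis, rhos)
    out = {"n_subjects": n_subjects,
           "coef_phi": reg["coef"]["phi"], "se_phi": reg["se"]["phi"],
           "coef_prior": reg["coef"]["prior"], "se_prior": reg["se"]["prior"],
           "true_coef_phi": spec.rt_coef_phi,
           "true_coef_prior": spec.rt_coef_prior}
    out["phi_within_2se"] = bool(abs(out["coef_phi"] - spec.rt_coef_phi) <= 2 * out["se_phi"])
    out["prior_within_2se"] = bool(abs(out["coef_prior"] - spec.rt_coef_prior) <= 2 * out["se_prior"])
    return out


def pipeline_determinism(seed: int = 0) -> dict:
    """Run the miniature pipeline twice into separate directories and compare
    every artifact byte for byte."""
    from .pipeline import PipelineConfig, run_pipeline, small_cohort_config

    def digest(out_dir: Path) -> dict:
        d = {}
        for f in sorted(out_dir.rglob("*")):
            if f.is_file():
                d[str(f.relative_to(out_dir))] = hashlib.sha256(f.read_bytes()).hexdigest()
        return d

    with tempfile.TemporaryDirectory() as tmp:
        cfg = PipelineConfig(cohort=small_cohort_config(), seed=seed,
                             fit=FitConfig(n_starts=2, k_grid=(3,),
                                           fixed={"beta": 8.0}, max_iter=60))
        d1 = dataclasses.replace(cfg, out_dir=str(Path(tmp) / "a"))
        d2 = dataclasses.replace(cfg, out_dir=str(Path(tmp) / "b"))
        run_pipeline(d1)
        run_pipeline(d2)
        h1, h2 = digest(Path(tmp) / "a"), digest(Path(tmp) / "b")
    return {"identical": bool(h1 == h2), "n_files": len(h1)}
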